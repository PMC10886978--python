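"""I/O and data-model tests: TSV round-trips, validation, cis subsetting."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from cismr.sumstats import (
    GeneRegion,
    LDMatrix,
    RegionData,
    TraitMeta,
    VariantAssoc,
    read_ld_matrix,
    read_sumstats,
    subset_region,
    write_ld_matrix,
    write_sumstats,
)
from conftest import make_variant

META = TraitMeta("prot", "quantitative", "CSF", "log-RFU")


def write_tsv(path, header, rows):
    lines = ["\t".join(header)] + ["\t".join(str(x) for x in r) for r in rows]
    path.write_text("\n".join(lines) + "\n")


HEADER = ["chromosome", "base_pair_location", "effect_allele", "other_allele",
          "beta", "standard_error", "effect_allele_frequency", "p_value",
          "rsid", "n"]


class TestReadSumstats:
    def test_well_formed_file_round_trips(self, tmp_path):
        region = RegionData(META, [
            make_variant("rs1", pos=100), make_variant("rs2", pos=200, beta=-0.2),
            make_variant("rs3", pos=300, ea="C", oa="T"),
        ])
        path = tmp_path / "s.tsv"
        write_sumstats(region, path)
        back = read_sumstats(path, META)
        assert len(back) == 3 and back.n_dropped == 0
        for a, b in zip(region.variants, back.variants):
            assert a.variant_id == b.variant_id
            assert (a.effect_allele, a.other_allele) == (b.effect_allele, b.other_allele)
            assert a.beta == pytest.approx(b.beta, rel=1e-9)
            assert a.eaf == pytest.approx(b.eaf, rel=1e-9)
            assert a.n == b.n

    def test_invalid_rows_dropped_and_counted(self, tmp_path):
        path = tmp_path / "s.tsv"
        p_ok = 2 * stats.norm.sf(5.0)  # consistent with beta/se = 5
        write_tsv(path, HEADER, [
            ["1", 100, "A", "G", 0.1, 0.02, 0.3, p_ok, "rs1", 1000],
            ["1", 200, "A", "G", 0.1, 0.0, 0.3, p_ok, "rs2", 1000],   # se = 0
            ["1", 300, "A", "A", 0.1, 0.02, 0.3, p_ok, "rs3", 1000],  # same alleles
            ["1", 400, "AT", "G", 0.1, 0.02, 0.3, p_ok, "rs4", 1000],  # indel
            ["1", 500, "A", "G", 0.1, 0.02, 1.3, p_ok, "rs5", 1000],  # eaf > 1
        ])
        region = read_sumstats(path, META)
        assert len(region) == 1 and region.n_dropped == 4

    def test_missing_pvalue_recomputed_from_z(self, tmp_path):
        path = tmp_path / "s.tsv"
        write_tsv(path, HEADER[:6], [["1", 100, "A", "G", 0.3, 0.1]])
        v = read_sumstats(path, META).variants[0]
        assert v.pvalue == pytest.approx(2 * stats.norm.sf(3.0), rel=1e-9)

    def test_inconsistent_pvalue_dropped(self, tmp_path):
        path = tmp_path / "s.tsv"
        write_tsv(path, HEADER, [
            ["1", 100, "A", "G", 0.3, 0.1, 0.3, 0.5, "rs1", 1000],  # true p ~ 0.0027
        ])
        with pytest.raises(ValueError, match="no valid rows"):
            read_sumstats(path, META)

    def test_missing_mandatory_column_errors(self, tmp_path):
        path = tmp_path / "s.tsv"
        write_tsv(path, ["chromosome", "base_pair_location", "beta"], [["1", 1, 0.1]])
        with pytest.raises(ValueError, match="mandatory"):
            read_sumstats(path, META)

    def test_unreadable_file_errors(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_sumstats(tmp_path / "absent.tsv", META)


class TestLDMatrix:
    def test_identity_round_trip(self, tmp_path):
        path = tmp_path / "ld.tsv"
        write_ld_matrix(LDMatrix(["v1", "v2"], np.eye(2)), path)
        ld = read_ld_matrix(path)
        assert ld.variant_ids == ["v1", "v2"]
        assert ld.r[0, 1] == 0.0

    def test_asymmetry_averaged(self, tmp_path):
        path = tmp_path / "ld.tsv"
        path.write_text("\tv1\tv2\nv1\t1.0\t0.5\nv2\t0.52\t1.0\n")
        ld = read_ld_matrix(path)
        assert ld.r[0, 1] == pytest.approx(0.51)
        assert ld.r[1, 0] == pytest.approx(0.51)

    def test_non_square_rejected(self, tmp_path):
        path = tmp_path / "ld.tsv"
        path.write_text("\tv1\tv2\tv3\nv1\t1\t0\t0\nv2\t0\t1\t0\n")
        with pytest.raises(ValueError, match="square"):
            read_ld_matrix(path)

    def test_header_mismatch_rejected(self, tmp_path):
        path = tmp_path / "ld.tsv"
        path.write_text("\tv1\tv2\nv1\t1\t0\nvX\t0\t1\n")
        with pytest.raises(ValueError, match="disagree"):
            read_ld_matrix(path)

    def test_r2_and_submatrix(self):
        ld = LDMatrix(["a", "b", "c"], np.array([[1, 0.5, 0.1], [0.5, 1, 0.2], [0.1, 0.2, 1]]))
        assert ld.r2("a", "b") == pytest.approx(0.25)
        sub = ld.submatrix(["c", "a"])
        assert sub.variant_ids == ["c", "a"]
        assert sub.r[0, 1] == pytest.approx(0.1)


class TestSubsetRegion:
    GENE = GeneRegion("G1", "1", 2_000_000, 2_010_000, cis_flank=1_000_000)

    def region(self, positions, chrom="1"):
        return RegionData(META, [
            make_variant(f"rs{i}", chrom=chrom, pos=p) for i, p in enumerate(positions)
        ])

    def test_inside_window_retained(self):
        assert len(subset_region(self.region([1_200_000]), self.GENE)) == 1

    def test_outside_window_excluded(self):
        assert len(subset_region(self.region([3_100_000]), self.GENE)) == 0

    def test_boundaries_inclusive_with_zero_flank(self):
        gene = GeneRegion("G1", "1", 2_000_000, 2_010_000, cis_flank=0)
        kept = subset_region(self.region([1_999_999, 2_000_000, 2_010_000, 2_010_001]), gene)
        assert [v.pos for v in kept.variants] == [2_000_000, 2_010_000]

    def test_other_chromosome_excluded(self):
        assert len(subset_region(self.region([2_000_000], chrom="2"), self.GENE)) == 0

    def test_ld_subset_follows_variants(self):
        ld = LDMatrix(["rs0", "rs1"], np.array([[1.0, 0.4], [0.4, 1.0]]))
        region = RegionData(META, [
            make_variant("rs0", pos=1_500_000), make_variant("rs1", pos=9_000_000)
        ], ld)
        sub = subset_region(region, self.GENE)
        assert sub.ld.variant_ids == ["rs0"]

    @given(flanks=st.lists(st.integers(0, 3_000_000), min_size=2, max_size=2),
           positions=st.lists(st.integers(1, 6_000_000), min_size=1, max_size=12,
                              unique=True))
    def test_idempotent_and_monotone_in_flank(self, flanks, positions):
        region = self.region(sorted(positions))
        small, large = sorted(flanks)
        g_small = GeneRegion("G", "1", 2_000_000, 2_010_000, cis_flank=small)
        g_large = GeneRegion("G", "1", 2_000_000, 2_010_000, cis_flank=large)
        once = subset_region(region, g_large)
        assert subset_region(once, g_large).variant_ids == once.variant_ids
        assert len(subset_region(region, g_small)) <= len(once)


class TestValidation:
    def test_variant_invariants(self):
        with pytest.raises(ValueError):
            make_variant(se=-1.0)
        with pytest.raises(ValueError):
            make_variant(ea="A", oa="A")
        with pytest.raises(ValueError):
            make_variant(eaf=0.0)
        with pytest.raises(ValueError):
            make_variant(pvalue=0.0)

    def test_trait_meta_case_control_rules(self):
        with pytest.raises(ValueError):
            TraitMeta("t", "binary")
        with pytest.raises(ValueError):
            TraitMeta("t", "quantitative", n_cases=10, n_controls=10)
        meta = TraitMeta("t", "binary", n_cases=100, n_controls=200)
        assert meta.is_binary

    def test_region_rejects_mismatched_ld(self):
        ld = LDMatrix(["a"], np.eye(1))
        with pytest.raises(ValueError, match="match"):
            RegionData(META, [make_variant("rs1"), make_variant("rs2", pos=2)], ld)

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            RegionData(META, [make_variant("rs1"), make_variant("rs1", pos=2)])

    def test_gene_region_interval_clips_at_one(self):
        gene = GeneRegion("G", "1", 100, 200, cis_flank=1_000)
        assert gene.cis_interval == (1, 1_200)
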