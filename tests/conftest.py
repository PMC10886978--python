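"""Shared fixtures and helpers for the test suite."""

from dataclasses import replace
from pathlib import Path

import numpy as np
import pytest
import yaml
from hypothesis import HealthCheck, settings

from cismr.harmonise import HarmonisedPair, InstrumentSet
from cismr.simulate import ScenarioConfig, simulate_study
from cismr.sumstats import TraitMeta, VariantAssoc, write_ld_matrix, write_sumstats

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_variant(variant_id="rs1", chrom="1", pos=1_000_000, ea="A", oa="G",
                 beta=0.1, se=0.02, eaf=0.3, pvalue=None, n=10_000):
    return VariantAssoc(variant_id, chrom, pos, ea, oa, beta, se, eaf, pvalue, n)


def make_instrument_set(bx, by, sy, sx=None, binary=False):
    """Instrument set from effect arrays, for estimator tests."""
    bx, by, sy = map(np.asarray, (bx, by, sy))
    sx = np.full(len(bx), 0.01) if sx is None else np.asarray(sx)
    pairs = [
        HarmonisedPair(f"v{i + 1}", float(bx[i]), float(sx[i]), float(by[i]),
                       float(sy[i]), 0.3, 0.3, "aligned", "A", "G")
        for i in range(len(bx))
    ]
    outcome = (
        TraitMeta("out", "binary", "none", "log-odds", 5000, 5000)
        if binary else TraitMeta("out")
    )
    return InstrumentSet(TraitMeta("exp"), outcome, pairs)


@pytest.fixture
def variant_factory():
    return make_variant


def write_study_config(tmp_path: Path, seed: int = 11, tissues=("CSF", "brain"),
                       with_plasma_followup: bool = True,
                       true_pairs=frozenset({("protein_1", "out1")})) -> Path:
    """Write a small simulated study (TSVs + LD + YAML config) to disk."""
    cfg = ScenarioConfig(scenario="H4_causal", n_exp=100_000, n_out=100_000, seed=seed)
    sim_tissues = tuple(tissues) + (("plasma",) if with_plasma_followup else ())
    study = simulate_study(cfg, n_proteins=2, outcome_ids=("out1", "out2"),
                           true_pairs=true_pairs, tissues=sim_tissues)
    exposures, followups = [], []
    for protein, tissue, region, gene in study["exposures"]:
        stem = f"{protein}_{tissue}"
        write_sumstats(region, tmp_path / f"{stem}.tsv")
        write_ld_matrix(region.ld, tmp_path / f"{stem}_ld.tsv")
        entry = {
            "protein": protein,
            "tissue": tissue,
            "sumstats": f"{stem}.tsv",
            "ld": f"{stem}_ld.tsv",
            "gene": {"gene_id": gene.gene_id, "chrom": gene.chrom,
                     "start": gene.start, "end": gene.end,
                     "cis_flank": gene.cis_flank},
        }
        (followups if tissue == "plasma" else exposures).append(entry)
    outcomes = []
    for trait_id, region in study["outcomes"].items():
        write_sumstats(region, tmp_path / f"{trait_id}.tsv")
        outcomes.append({"trait_id": trait_id, "sumstats": f"{trait_id}.tsv"})
    config = {
        "seed": seed,
        "exposures": exposures,
        "followups": followups,
        "outcomes": outcomes,
    }
    path = tmp_path / "config.yaml"
    path.write_text(yaml.safe_dump(config))
    return path
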