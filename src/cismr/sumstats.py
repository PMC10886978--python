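"""Summary-statistics data model and I/O.

The package works exclusively with GWAS *summary* statistics: per-variant
marginal associations (beta, SE, p, allele frequency, sample size) for one
trait, restricted to a cis locus around a gene, optionally accompanied by a
signed LD correlation matrix over the same variants.

Conventions
-----------
* Coordinates are 1-based; interval endpoints are inclusive (the usual GWAS
  summary-statistics convention).
* Alleles are single nucleotides over {A, C, G, T}; indels and multi-allelic
  records are rejected at read time.
* The on-disk dialect is a GWAS-SSF-style tab-separated file with columns
  ``chromosome, base_pair_location, effect_allele, other_allele, beta,
  standard_error`` (mandatory) and ``effect_allele_frequency, p_value, rsid,
  n`` (optional).  LD matrices are plain-text delimited square matrices whose
  first row and first column carry the variant IDs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VariantAssoc",
    "TraitMeta",
    "LDMatrix",
    "RegionData",
    "GeneRegion",
    "read_sumstats",
    "write_sumstats",
    "read_ld_matrix",
    "write_ld_matrix",
    "subset_region",
    "pvalue_from_z",
]

VALID_ALLELES = frozenset("ACGT")
VALID_TISSUES = frozenset(
    {"CSF", "brain", "plasma", "cortex", "hippocampus", "spinal_cord", "none"}
)

#: smallest p-value stored; normal-tail p-values below this underflow double
#: precision and are clipped (z-scores remain exact and are what downstream
#: computations use).
P_FLOOR = 1e-300

SSF_MANDATORY = [
    "chromosome",
    "base_pair_location",
    "effect_allele",
    "other_allele",
    "beta",
    "standard_error",
]
SSF_OPTIONAL = ["effect_allele_frequency", "p_value", "rsid", "n"]


def pvalue_from_z(z: float) -> float:
    """Two-sided normal p-value 2*Phi(-|z|), clipped away from zero."""
    p = math.erfc(abs(z) / math.sqrt(2.0))
    return max(p, P_FLOOR)


@dataclass(frozen=True, slots=True)
class VariantAssoc:
    """One variant's marginal association with one trait.

    ``beta`` is the effect of each additional copy of ``effect_allele`` on the
    trait scale; ``eaf`` is the effect-allele frequency.  ``pvalue`` defaults
    to the two-sided normal approximation from beta/se when not supplied.
    """

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    eaf: Optional[float] = None
    pvalue: Optional[float] = None
    n: Optional[int] = None

    def __post_init__(self):
        if self.effect_allele not in VALID_ALLELES or self.other_allele not in VALID_ALLELES:
            raise ValueError(f"{self.variant_id}: alleles must be single nucleotides ACGT")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.variant_id}: effect and other allele identical")
        if not (self.se > 0 and math.isfinite(self.se)):
            raise ValueError(f"{self.variant_id}: se must be positive and finite")
        if not math.isfinite(self.beta):
            raise ValueError(f"{self.variant_id}: beta must be finite")
        if self.pos < 1:
            raise ValueError(f"{self.variant_id}: position must be >= 1")
        if self.eaf is not None and not (0.0 < self.eaf < 1.0):
            raise ValueError(f"{self.variant_id}: eaf must lie in (0,1)")
        if self.n is not None and self.n < 1:
            raise ValueError(f"{self.variant_id}: n must be a positive integer")
        if self.pvalue is None:
            object.__setattr__(self, "pvalue", pvalue_from_z(self.beta / self.se))
        elif not (0.0 < self.pvalue <= 1.0):
            raise ValueError(f"{self.variant_id}: pvalue must lie in (0,1]")

    @property
    def z(self) -> float:
        return self.beta / self.se

    @property
    def maf(self) -> Optional[float]:
        return None if self.eaf is None else min(self.eaf, 1.0 - self.eaf)

    def pvalue_consistent(self, rel_tol: float = 0.10) -> bool:
        """Check the stored p against 2*Phi(-|z|) on the log10 scale.

        Returns True when either is below printed double precision or when
        -log10(p) agrees within ``rel_tol`` relative (0.05 absolute floor, so
        p ~ 1 does not trip the relative check).
        """
        expected = pvalue_from_z(self.z)
        if self.pvalue <= 10 * P_FLOOR or expected <= 10 * P_FLOOR:
            return True
        lo, le = -math.log10(self.pvalue), -math.log10(expected)
        return abs(lo - le) <= max(rel_tol * le, 0.05)


@dataclass(frozen=True)
class TraitMeta:
    """Identity and scale of one trait (a protein, a transcript, an outcome)."""

    trait_id: str
    trait_type: str = "quantitative"  # {"quantitative", "binary"}
    tissue: str = "none"
    unit: str = ""
    n_cases: Optional[int] = None
    n_controls: Optional[int] = None

    def __post_init__(self):
        if self.trait_type not in ("quantitative", "binary"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        if self.tissue not in VALID_TISSUES:
            raise ValueError(f"unknown tissue {self.tissue!r}")
        if self.trait_type == "binary":
            if not (self.n_cases and self.n_controls):
                raise ValueError("binary traits require n_cases and n_controls")
        elif self.n_cases is not None or self.n_controls is not None:
            raise ValueError("quantitative traits must not carry case/control counts")

    @property
    def is_binary(self) -> bool:
        return self.trait_type == "binary"


@dataclass
class LDMatrix:
    """Signed pairwise correlation matrix r over an ordered set of variants."""

    variant_ids: list
    r: np.ndarray

    def __post_init__(self):
        self.variant_ids = list(self.variant_ids)
        self.r = np.asarray(self.r, dtype=float)
        m = len(self.variant_ids)
        if self.r.shape != (m, m):
            raise ValueError(f"LD matrix shape {self.r.shape} does not match {m} variant ids")
        if m and not np.allclose(self.r, self.r.T, atol=1e-8):
            raise ValueError("LD matrix not symmetric to 1e-8")
        if m and not np.allclose(np.diag(self.r), 1.0, atol=1e-8):
            raise ValueError("LD matrix diagonal must be 1")
        if m and np.max(np.abs(self.r)) > 1.0 + 1e-8:
            raise ValueError("LD correlations must lie in [-1, 1]")
        self._index = {v: i for i, v in enumerate(self.variant_ids)}
        if len(self._index) != m:
            raise ValueError("duplicate variant ids in LD matrix")

    def __len__(self):
        return len(self.variant_ids)

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def r2(self, a: str, b: str) -> float:
        return float(self.r[self._index[a], self._index[b]] ** 2)

    def submatrix(self, ids: Sequence[str]) -> "LDMatrix":
        idx = [self._index[v] for v in ids]
        return LDMatrix(list(ids), self.r[np.ix_(idx, idx)])


@dataclass
class RegionData:
    """All variants for one trait in one locus, optionally with LD."""

    trait: TraitMeta
    variants: list
    ld: Optional[LDMatrix] = None
    n_dropped: int = 0
    drop_reasons: dict = field(default_factory=dict)

    def __post_init__(self):
        ids = [v.variant_id for v in self.variants]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate variant ids in region")
        if self.ld is not None:
            if len(self.ld) != len(self.variants) or self.ld.variant_ids != ids:
                raise ValueError("LD matrix does not match region variant order")

    def __len__(self):
        return len(self.variants)

    @property
    def variant_ids(self) -> list:
        return [v.variant_id for v in self.variants]

    def by_id(self) -> dict:
        return {v.variant_id: v for v in self.variants}

    def with_variants(self, variants: Iterable[VariantAssoc]) -> "RegionData":
        """Reslice to the given variants (must be a subset), keeping order."""
        variants = list(variants)
        ld = self.ld.submatrix([v.variant_id for v in variants]) if self.ld is not None else None
        return RegionData(self.trait, variants, ld, self.n_dropped, dict(self.drop_reasons))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "chromosome": v.chrom,
                "base_pair_location": v.pos,
                "effect_allele": v.effect_allele,
                "other_allele": v.other_allele,
                "beta": v.beta,
                "standard_error": v.se,
                "effect_allele_frequency": v.eaf,
                "p_value": v.pvalue,
                "rsid": v.variant_id,
                "n": v.n,
            }
            for v in self.variants
        ]
        return pd.DataFrame(rows, columns=SSF_MANDATORY + SSF_OPTIONAL)


@dataclass(frozen=True)
class GeneRegion:
    """Gene coordinates plus the cis flank defining the instrument window."""

    gene_id: str
    chrom: str
    start: int
    end: int
    cis_flank: int = 1_000_000

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")
        if self.start < 1 or self.cis_flank < 0:
            raise ValueError(f"{self.gene_id}: invalid coordinates")

    @property
    def cis_interval(self) -> tuple:
        """Inclusive [start - flank, end + flank], clipped at 1."""
        return (max(1, self.start - self.cis_flank), self.end + self.cis_flank)

    def contains(self, chrom: str, pos: int) -> bool:
        lo, hi = self.cis_interval
        return chrom == self.chrom and lo <= pos <= hi


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_sumstats(path, meta: TraitMeta) -> RegionData:
    """Read a GWAS-SSF-style TSV into a validated :class:`RegionData`.

    Rows violating the per-variant invariants (non-ACGT or identical alleles,
    se <= 0, eaf outside (0,1), p inconsistent with beta/se by more than 10%
    on the -log10 scale) are dropped and counted in ``drop_reasons``.  A
    missing p-value is recomputed as 2*Phi(-|beta/se|).
    """
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str, "rsid": str})
    missing = [c for c in SSF_MANDATORY if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory columns {missing}")
    variants, reasons = [], {}
    seen = set()
    for row in df.itertuples(index=False):
        d = row._asdict()
        try:
            rsid = d.get("rsid")
            pos = int(d["base_pair_location"])
            ea = str(d["effect_allele"]).upper()
            oa = str(d["other_allele"]).upper()
            vid = (
                str(rsid)
                if rsid is not None and not pd.isna(rsid)
                else f"{d['chromosome']}:{pos}:{oa}:{ea}"
            )
            eaf = d.get("effect_allele_frequency")
            pval = d.get("p_value")
            n = d.get("n")
            v = VariantAssoc(
                variant_id=vid,
                chrom=str(d["chromosome"]),
                pos=pos,
                effect_allele=ea,
                other_allele=oa,
                beta=float(d["beta"]),
                se=float(d["standard_error"]),
                eaf=None if eaf is None or pd.isna(eaf) else float(eaf),
                pvalue=None if pval is None or pd.isna(pval) else float(pval),
                n=None if n is None or pd.isna(n) else int(n),
            )
        except (ValueError, TypeError) as exc:
            reasons[str(exc)] = reasons.get(str(exc), 0) + 1
            continue
        if d.get("p_value") is not None and not pd.isna(d.get("p_value")):
            if not v.pvalue_consistent():
                key = f"{v.variant_id}: pvalue inconsistent with beta/se"
                reasons[key] = reasons.get(key, 0) + 1
                continue
        if v.variant_id in seen:
            key = f"{v.variant_id}: duplicate variant id"
            reasons[key] = reasons.get(key, 0) + 1
            continue
        seen.add(v.variant_id)
        variants.append(v)
    if not variants:
        raise ValueError(f"{path}: no valid rows")
    return RegionData(meta, variants, n_dropped=sum(reasons.values()), drop_reasons=reasons)


def write_sumstats(region: RegionData, path) -> None:
    region.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_ld_matrix(path) -> LDMatrix:
    """Read a delimited square correlation matrix with ID headers.

    The matrix is symmetrized as (M + M')/2, the diagonal forced to 1 and
    off-diagonal magnitudes clipped to 1.  Row and column IDs must agree.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    row_ids = [str(i) for i in df.index]
    col_ids = [str(c) for c in df.columns]
    if df.shape[0] != df.shape[1]:
        raise ValueError(f"{path}: LD matrix is not square {df.shape}")
    if row_ids != col_ids:
        raise ValueError(f"{path}: row and column variant IDs disagree")
    m = df.to_numpy(dtype=float)
    m = (m + m.T) / 2.0
    m = np.clip(m, -1.0, 1.0)
    np.fill_diagonal(m, 1.0)
    return LDMatrix(row_ids, m)


def write_ld_matrix(ld: LDMatrix, path) -> None:
    pd.DataFrame(ld.r, index=ld.variant_ids, columns=ld.variant_ids).to_csv(
        path, sep="\t", float_format="%.10g"
    )


def subset_region(data: RegionData, region: GeneRegion) -> RegionData:
    """Restrict a region to the gene's cis interval (inclusive), keeping order."""
    kept = [v for v in data.variants if region.contains(v.chrom, v.pos)]
    return data.with_variants(kept)
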