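"""Cis instrument selection: significance filter, LD clumping, strength diagnostics.

Instruments are cis-QTLs: variants associated with the molecular trait at
genome-wide significance (p < 5e-8 by default) inside the gene's cis window.
Approximate independence is enforced by greedy LD clumping (r^2 < 0.01 within
a 1 Mb window by default), and instrument strength is summarised by per-variant
and cumulative F-statistics plus the proportion of variance explained (PVE),
with F > 20 taken as acceptable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .sumstats import RegionData, VariantAssoc

__all__ = [
    "ClumpConfig",
    "InstrumentDiagnostics",
    "clump",
    "variant_f_stat",
    "variance_explained",
    "F_ACCEPTABLE",
]

#: instrument-strength rule of thumb: F above this is considered acceptable
F_ACCEPTABLE = 20.0


@dataclass(frozen=True)
class ClumpConfig:
    """Thresholds for significance filtering and greedy LD clumping."""

    p_threshold: float = 5e-8
    r2_threshold: float = 0.01
    clump_window: int = 1_000_000

    def __post_init__(self):
        if not (0 < self.p_threshold <= 1):
            raise ValueError("p_threshold must lie in (0,1]")
        if not (0 < self.r2_threshold <= 1):
            raise ValueError("r2_threshold must lie in (0,1]")
        if self.clump_window <= 0:
            raise ValueError("clump_window must be positive")


@dataclass(frozen=True)
class InstrumentDiagnostics:
    """Strength summary for a clumped instrument set."""

    per_variant_f: tuple
    cumulative_f: float
    pve: float
    n_instruments: int

    @property
    def weak(self) -> bool:
        return self.cumulative_f <= F_ACCEPTABLE


def clump(region: RegionData, cfg: ClumpConfig = ClumpConfig()) -> list:
    """Greedy LD clumping of significant variants.

    Candidates (p < ``cfg.p_threshold``) are sorted by ascending p-value, ties
    broken by position then variant id.  The best remaining candidate becomes
    an index variant; every remaining candidate with r^2 >= ``r2_threshold``
    against it *and* within ``clump_window`` base pairs of it is removed.
    Index variants are returned in selection order.  Both the LD and the
    distance condition must hold for removal: correlated variants beyond the
    window, or nearby but uncorrelated variants, survive.
    """
    candidates = [v for v in region.variants if v.pvalue < cfg.p_threshold]
    if not candidates:
        return []
    if region.ld is None:
        if len(candidates) > 1:
            raise ValueError("clumping requires an LD matrix when >1 candidate")
        return candidates
    for v in candidates:
        if v.variant_id not in region.ld:
            raise ValueError(f"candidate {v.variant_id} absent from LD matrix")
    candidates.sort(key=lambda v: (v.pvalue, v.pos, v.variant_id))
    index_variants = []
    remaining = candidates
    while remaining:
        lead = remaining[0]
        index_variants.append(lead)
        remaining = [
            v
            for v in remaining[1:]
            if not (
                region.ld.r2(lead.variant_id, v.variant_id) >= cfg.r2_threshold
                and abs(v.pos - lead.pos) <= cfg.clump_window
            )
        ]
    return index_variants


def variant_f_stat(v: VariantAssoc) -> float:
    """Single-variant instrument F-statistic, (beta/se)^2."""
    return (v.beta / v.se) ** 2


def variance_explained(instruments: list) -> InstrumentDiagnostics:
    """PVE and cumulative F for an (approximately independent) instrument set.

    Per variant, r2_j = 2*eaf_j*(1-eaf_j)*beta_j^2 on a standardized trait
    (var(y) = 1); PVE is their sum.  The cumulative F-statistic is
    ``pve*(n - k - 1) / ((1 - pve)*k)`` with k instruments and n the minimum
    instrument sample size (conservative when sample sizes differ).
    """
    if not instruments:
        raise ValueError("empty instrument list")
    for v in instruments:
        if v.eaf is None:
            raise ValueError(f"{v.variant_id}: eaf required for variance explained")
        if v.n is None:
            raise ValueError(f"{v.variant_id}: n required for variance explained")
    pve = sum(2.0 * v.eaf * (1.0 - v.eaf) * v.beta**2 for v in instruments)
    if pve >= 1.0:
        raise ValueError(f"pve {pve:.3f} >= 1; check effect scale")
    k = len(instruments)
    n = min(v.n for v in instruments)
    cumulative_f = pve * (n - k - 1) / ((1.0 - pve) * k)
    return InstrumentDiagnostics(
        per_variant_f=tuple(variant_f_stat(v) for v in instruments),
        cumulative_f=cumulative_f,
        pve=pve,
        n_instruments=k,
    )
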