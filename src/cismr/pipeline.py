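"""Study orchestration: primary cis-MR, follow-up MR, coloc, triangulation.

The full design mirrors a tissue-specific proteome-wide MR study:

1. **Primary analysis** — for every protein instrumented in CSF or brain and
   every outcome: restrict to the cis window, filter to genome-wide
   significance, intersect with the outcome dataset, LD-clump, flag weak
   instruments (F <= 20), harmonise, and estimate the effect (Wald ratio for
   a single instrument, random-effects IVW otherwise, MR-Egger and weighted
   median as sensitivity analyses from three instruments).  Benjamini-
   Hochberg FDR is applied within the primary family (CSF + brain pooled by
   default; a per-tissue switch is available).
2. **Follow-up analysis** — pairs significant at pFDR < 0.05 are re-examined
   with plasma pQTL and brain-expression eQTL instruments; eQTL effects
   supplied as z-scores are converted to beta/SE assuming var(y) = 1.  FDR is
   computed separately for the plasma and the expression family.
3. **Colocalization** — pairs significant in both CSF and brain, and pairs
   whose follow-up is also significant, are taken to single-causal-variant
   colocalization per eligible tissue.
4. **Triangulation** — per protein-outcome pair, tissue-level significance
   and effect directions are classified as concordant / discordant multi-
   tissue, single-tissue, or null.

Identical configuration and seed give byte-identical output tables.
"""

from __future__ import annotations

import hashlib
import json
import math
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .coloc import ColocConfig, ColocResult, coloc_abf, coloc_eligibility
from .estimators import MRResult, fit_mr
from .harmonise import build_instrument_set, harmonise_regions
from .instruments import ClumpConfig, clump, variance_explained
from .sumstats import (
    GeneRegion,
    RegionData,
    TraitMeta,
    VariantAssoc,
    read_ld_matrix,
    read_sumstats,
    subset_region,
)

__all__ = [
    "PipelineConfig",
    "ExposureSpec",
    "OutcomeSpec",
    "AssociationRecord",
    "ConcordanceRecord",
    "ColocRow",
    "bh_fdr",
    "zscore_to_effect",
    "convert_z_region",
    "analyse_pair",
    "run_primary",
    "run_followup",
    "run_pipeline",
    "classify_concordance",
    "render_reports",
    "load_config",
]

PRIMARY_TISSUES = {"CSF", "brain"}


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, returned in input order.

    q_i = p_(i) * m / i for the sorted p-values, made monotone non-decreasing
    from the largest down and capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def zscore_to_effect(z: float, eaf: float, n: int) -> tuple:
    """Convert a z-score to (beta, se) assuming a standardized trait.

    beta = z / sqrt(2*eaf*(1-eaf)*(n + z^2)), se = 1/sqrt(2*eaf*(1-eaf)*(n + z^2)),
    so beta/se = z exactly.  Used for eQTL datasets distributed as z-scores.
    """
    if not (0.0 < eaf < 1.0):
        raise ValueError("eaf must lie in (0, 1)")
    if n <= 1:
        raise ValueError("n must exceed 1")
    denom = math.sqrt(2.0 * eaf * (1.0 - eaf) * (n + z * z))
    return z / denom, 1.0 / denom


def convert_z_region(region: RegionData) -> RegionData:
    """Reinterpret a region whose beta column carries z-scores.

    Every variant needs eaf and n; the stored SE is discarded and both beta
    and SE are recomputed on the standardized (var(y) = 1) scale.
    """
    converted = []
    for v in region.variants:
        if v.eaf is None or v.n is None:
            raise ValueError(f"{v.variant_id}: z-score conversion needs eaf and n")
        beta, se = zscore_to_effect(v.beta, v.eaf, v.n)
        converted.append(
            VariantAssoc(
                variant_id=v.variant_id, chrom=v.chrom, pos=v.pos,
                effect_allele=v.effect_allele, other_allele=v.other_allele,
                beta=beta, se=se, eaf=v.eaf, n=v.n,
            )
        )
    return RegionData(region.trait, converted, region.ld, region.n_dropped,
                      dict(region.drop_reasons))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExposureSpec:
    """One molecular-QTL dataset: a protein (or transcript) in one tissue."""

    protein: str
    tissue: str
    sumstats: str
    gene: GeneRegion
    ld: Optional[str] = None
    effects_as_z: bool = False
    unit: str = "log-RFU"

    def meta(self) -> TraitMeta:
        return TraitMeta(self.protein, "quantitative", self.tissue, self.unit)


@dataclass(frozen=True)
class OutcomeSpec:
    trait_id: str
    sumstats: str
    trait_type: str = "quantitative"
    unit: str = "SD"
    n_cases: Optional[int] = None
    n_controls: Optional[int] = None

    def meta(self) -> TraitMeta:
        return TraitMeta(self.trait_id, self.trait_type, "none", self.unit,
                         self.n_cases, self.n_controls)


@dataclass
class PipelineConfig:
    """Everything a run needs: thresholds, families, seed, and input paths."""

    exposures: list = field(default_factory=list)   # ExposureSpec, CSF/brain
    followups: list = field(default_factory=list)   # ExposureSpec, plasma/eQTL
    outcomes: list = field(default_factory=list)    # OutcomeSpec
    clump: ClumpConfig = field(default_factory=ClumpConfig)
    coloc: ColocConfig = field(default_factory=ColocConfig)
    fdr_alpha: float = 0.05
    f_min: float = 20.0
    drop_weak: bool = False
    family_mode: str = "pooled"  # primary family: "pooled" CSF+brain or "per_tissue"
    clump_before_intersect: bool = False
    palindromic_maf_limit: float = 0.42
    n_boot: int = 1000
    pph_threshold: float = 0.5
    run_coloc: bool = True
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.fdr_alpha < 1.0):
            raise ValueError("fdr_alpha must lie in (0, 1)")
        if self.family_mode not in ("pooled", "per_tissue"):
            raise ValueError("family_mode must be 'pooled' or 'per_tissue'")
        for e in self.exposures:
            if e.tissue not in PRIMARY_TISSUES:
                raise ValueError(f"primary exposure tissue must be CSF/brain, got {e.tissue}")

    def echo(self) -> dict:
        """Threshold echo for the run manifest."""
        return {
            "p_threshold": self.clump.p_threshold,
            "r2_threshold": self.clump.r2_threshold,
            "clump_window": self.clump.clump_window,
            "f_min": self.f_min,
            "drop_weak": self.drop_weak,
            "fdr_alpha": self.fdr_alpha,
            "family_mode": self.family_mode,
            "coloc_priors": {"p1": self.coloc.p1, "p2": self.coloc.p2, "p12": self.coloc.p12},
            "coloc_prior_sd": {
                "quantitative": self.coloc.prior_sd_quant,
                "binary": self.coloc.prior_sd_binary,
            },
            "pph_threshold": self.pph_threshold,
            "palindromic_maf_limit": self.palindromic_maf_limit,
            "n_boot": self.n_boot,
        }


def _gene_from_dict(d: dict) -> GeneRegion:
    return GeneRegion(
        gene_id=d["gene_id"], chrom=str(d["chrom"]), start=int(d["start"]),
        end=int(d["end"]), cis_flank=int(d.get("cis_flank", 1_000_000)),
    )


def load_config(path) -> PipelineConfig:
    """Load a YAML run configuration; data paths resolve relative to it."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    base = path.parent

    def resolve(p):
        p = Path(p)
        return str(p if p.is_absolute() else base / p)

    def exposure(d):
        return ExposureSpec(
            protein=d["protein"], tissue=d["tissue"], sumstats=resolve(d["sumstats"]),
            gene=_gene_from_dict(d["gene"]),
            ld=resolve(d["ld"]) if d.get("ld") else None,
            effects_as_z=bool(d.get("effects_as_z", False)),
            unit=d.get("unit", "log-RFU"),
        )

    def outcome(d):
        return OutcomeSpec(
            trait_id=d["trait_id"], sumstats=resolve(d["sumstats"]),
            trait_type=d.get("trait_type", "quantitative"), unit=d.get("unit", "SD"),
            n_cases=d.get("n_cases"), n_controls=d.get("n_controls"),
        )

    kwargs = {}
    if "clump" in raw:
        kwargs["clump"] = ClumpConfig(**raw["clump"])
    if "coloc" in raw:
        kwargs["coloc"] = ColocConfig(**raw["coloc"])
    for key in (
        "fdr_alpha", "f_min", "drop_weak", "family_mode", "clump_before_intersect",
        "palindromic_maf_limit", "n_boot", "pph_threshold", "run_coloc", "seed",
    ):
        if key in raw:
            kwargs[key] = raw[key]
    return PipelineConfig(
        exposures=[exposure(d) for d in raw.get("exposures", [])],
        followups=[exposure(d) for d in raw.get("followups", [])],
        outcomes=[outcome(d) for d in raw.get("outcomes", [])],
        **kwargs,
    )


# ---------------------------------------------------------------------------
# per-analysis records
# ---------------------------------------------------------------------------

@dataclass
class AssociationRecord:
    """One protein-tissue-outcome MR analysis with its FDR annotation."""

    protein: str
    outcome: str
    tissue: str
    family: str  # "primary", "plasma", or "expression"
    method: str = ""  # primary estimator: wald_ratio or ivw
    results: dict = field(default_factory=dict)  # method name -> MRResult
    pvalue: Optional[float] = None
    pfdr: Optional[float] = None
    significant: bool = False
    direction: int = 0
    n_snps: int = 0
    pve: Optional[float] = None
    cumulative_f: Optional[float] = None
    weak_instrument: bool = False
    harmonisation_log: dict = field(default_factory=dict)
    skip_reason: Optional[str] = None

    @property
    def key(self) -> tuple:
        return (self.protein, self.outcome)


@dataclass(frozen=True)
class ConcordanceRecord:
    """Cross-tissue triangulation for one protein-outcome pair."""

    protein: str
    outcome: str
    tissues_significant: tuple
    directions: tuple  # aligned with tissues_significant
    classification: str


@dataclass(frozen=True)
class ColocRow:
    protein: str
    outcome: str
    tissue: str
    result: ColocResult


def _analysis_seed(base_seed: int, protein: str, tissue: str, outcome: str) -> int:
    tag = f"{protein}|{tissue}|{outcome}".encode()
    return int((base_seed * 1_000_003 + zlib.crc32(tag)) % (2**31 - 1))


def analyse_pair(
    protein: str,
    tissue: str,
    family: str,
    exposure_region: RegionData,
    gene: GeneRegion,
    outcome_region: RegionData,
    cfg: PipelineConfig,
) -> AssociationRecord:
    """One exposure-outcome MR analysis following the standard cis recipe.

    Failures that reflect the data rather than the configuration (no
    significant cis variant, nothing harmonisable) are recorded as skips with
    a reason code, not raised.
    """
    rec = AssociationRecord(protein=protein, outcome=outcome_region.trait.trait_id,
                            tissue=tissue, family=family)
    cis = subset_region(exposure_region, gene)
    if len(cis) == 0:
        rec.skip_reason = "no_cis_variants"
        return rec

    out_ids = set(outcome_region.variant_ids)
    if cfg.clump_before_intersect:
        clumped = clump(cis, cfg.clump)
        clumped = [v for v in clumped if v.variant_id in out_ids]
    else:
        shared = cis.with_variants([v for v in cis.variants if v.variant_id in out_ids])
        if len(shared) == 0:
            rec.skip_reason = "no_overlap_with_outcome"
            return rec
        clumped = clump(shared, cfg.clump)
    if not clumped:
        rec.skip_reason = "no_instruments"
        return rec

    if cfg.drop_weak:
        clumped = [v for v in clumped if (v.beta / v.se) ** 2 > cfg.f_min]
        if not clumped:
            rec.skip_reason = "weak_instruments"
            return rec

    try:
        diag = variance_explained(clumped)
        rec.pve = diag.pve
        rec.cumulative_f = diag.cumulative_f
        rec.weak_instrument = diag.cumulative_f <= cfg.f_min
    except ValueError:
        rec.weak_instrument = any((v.beta / v.se) ** 2 <= cfg.f_min for v in clumped)

    exposure_meta = TraitMeta(protein, "quantitative", tissue, "log-RFU")
    try:
        instr = build_instrument_set(
            clumped, outcome_region, exposure_meta, cfg.palindromic_maf_limit
        )
    except ValueError:
        rec.skip_reason = "no_harmonised_instruments"
        return rec

    seed = _analysis_seed(cfg.seed, protein, tissue, outcome_region.trait.trait_id)
    rec.results = fit_mr(instr, n_boot=cfg.n_boot, seed=seed)
    rec.harmonisation_log = dict(instr.log)
    rec.method = "wald_ratio" if "wald_ratio" in rec.results else "ivw"
    primary = rec.results[rec.method]
    rec.pvalue = primary.pvalue
    rec.direction = int(np.sign(primary.estimate))
    rec.n_snps = primary.n_snps
    return rec


# ---------------------------------------------------------------------------
# loading and the run itself
# ---------------------------------------------------------------------------

def _load_exposure(spec: ExposureSpec) -> RegionData:
    region = read_sumstats(spec.sumstats, spec.meta())
    if spec.ld:
        ld = read_ld_matrix(spec.ld)
        keep = [v for v in region.variants if v.variant_id in ld]
        region = RegionData(region.trait, keep,
                            ld.submatrix([v.variant_id for v in keep]),
                            region.n_dropped, dict(region.drop_reasons))
    if spec.effects_as_z:
        region = convert_z_region(region)
    return region


def _apply_fdr(records: list, families: dict, alpha: float) -> None:
    """Annotate pfdr/significant in place, one BH adjustment per family."""
    for _, group in families.items():
        tested = [r for r in group if r.skip_reason is None and r.pvalue is not None]
        if not tested:
            continue
        adj = bh_fdr([r.pvalue for r in tested])
        for r, q in zip(tested, adj):
            r.pfdr = float(q)
            r.significant = bool(q < alpha)


def _family_key_primary(cfg: PipelineConfig, rec: AssociationRecord) -> str:
    return rec.tissue if cfg.family_mode == "per_tissue" else "primary"


def run_primary_data(exposures: list, outcome_regions: dict,
                     cfg: PipelineConfig) -> list:
    """In-memory primary scan over (protein, tissue, RegionData, GeneRegion)
    exposures and a trait_id -> RegionData outcome map, with BH-FDR."""
    records = []
    for protein, tissue, region, gene in sorted(exposures, key=lambda e: (e[0], e[1])):
        for trait_id in sorted(outcome_regions):
            records.append(
                analyse_pair(protein, tissue, "primary", region, gene,
                             outcome_regions[trait_id], cfg)
            )
    families: dict = {}
    for r in records:
        families.setdefault(_family_key_primary(cfg, r), []).append(r)
    _apply_fdr(records=records, families=families, alpha=cfg.fdr_alpha)
    return records


def run_primary(cfg: PipelineConfig) -> list:
    """Primary CSF/brain MR scan with family-wise BH-FDR annotation."""
    outcome_regions = {
        o.trait_id: read_sumstats(o.sumstats, o.meta())
        for o in sorted(cfg.outcomes, key=lambda o: o.trait_id)
    }
    exposures = [
        (spec.protein, spec.tissue, _load_exposure(spec), spec.gene)
        for spec in sorted(cfg.exposures, key=lambda e: (e.protein, e.tissue))
    ]
    return run_primary_data(exposures, outcome_regions, cfg)


def run_followup(primary: list, cfg: PipelineConfig) -> list:
    """Plasma/expression MR restricted to primary-significant pairs.

    FDR is computed separately for the plasma family and the brain-expression
    family (cortex, hippocampus, spinal cord pooled).
    """
    significant_pairs = {r.key for r in primary if r.significant}
    if not significant_pairs or not cfg.followups:
        return []
    wanted_outcomes = sorted({o for (_, o) in significant_pairs})
    outcome_regions = {
        o.trait_id: read_sumstats(o.sumstats, o.meta())
        for o in sorted(cfg.outcomes, key=lambda o: o.trait_id)
        if o.trait_id in wanted_outcomes
    }
    records = []
    for spec in sorted(cfg.followups, key=lambda e: (e.protein, e.tissue)):
        targets = sorted(
            t for t in outcome_regions if (spec.protein, t) in significant_pairs
        )
        if not targets:
            continue
        region = _load_exposure(spec)
        family = "plasma" if spec.tissue == "plasma" else "expression"
        for trait_id in targets:
            records.append(
                analyse_pair(spec.protein, spec.tissue, family, region,
                             spec.gene, outcome_regions[trait_id], cfg)
            )
    families: dict = {}
    for r in records:
        families.setdefault(r.family, []).append(r)
    _apply_fdr(records=records, families=families, alpha=cfg.fdr_alpha)
    return records


def classify_concordance(records: list) -> list:
    """Cross-tissue direction accounting per protein-outcome pair."""
    grouped: dict = {}
    for r in records:
        grouped.setdefault(r.key, []).append(r)
    out = []
    for (protein, outcome) in sorted(grouped):
        sig = [r for r in grouped[(protein, outcome)] if r.significant]
        tissues = tuple(r.tissue for r in sorted(sig, key=lambda r: r.tissue))
        directions = tuple(
            r.direction for r in sorted(sig, key=lambda r: r.tissue)
        )
        if len(sig) == 0:
            cls = "null"
        elif len(sig) == 1:
            cls = "single_tissue"
        elif len(set(directions)) == 1:
            cls = "concordant_multi_tissue"
        else:
            cls = "discordant_multi_tissue"
        out.append(ConcordanceRecord(protein, outcome, tissues, directions, cls))
    return out


def run_coloc_stage(records: list, cfg: PipelineConfig) -> list:
    """Colocalize every eligible (protein, outcome, tissue) triple."""
    triples = coloc_eligibility(records)
    if not triples:
        return []
    exposure_specs = {
        (e.protein, e.tissue): e for e in list(cfg.exposures) + list(cfg.followups)
    }
    outcome_specs = {o.trait_id: o for o in cfg.outcomes}
    region_cache: dict = {}
    outcome_cache: dict = {}
    rows = []
    for protein, outcome, tissue in triples:
        spec = exposure_specs.get((protein, tissue))
        if spec is None:
            continue
        if (protein, tissue) not in region_cache:
            region_cache[(protein, tissue)] = _load_exposure(spec)
        if outcome not in outcome_cache:
            outcome_cache[outcome] = read_sumstats(
                outcome_specs[outcome].sumstats, outcome_specs[outcome].meta()
            )
        cis = subset_region(region_cache[(protein, tissue)], spec.gene)
        try:
            exp_sub, out_sub = harmonise_regions(
                cis, outcome_cache[outcome], cfg.palindromic_maf_limit
            )
        except ValueError:
            continue
        rows.append(ColocRow(protein, outcome, tissue, coloc_abf(exp_sub, out_sub, cfg.coloc)))
    return rows


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

MR_COLUMNS = [
    "protein", "tissue", "outcome", "family", "method", "n_snps", "estimate",
    "se", "ci_low", "ci_high", "pvalue", "Q", "I2", "odds_ratio", "or_ci_low",
    "or_ci_high", "pfdr", "significant", "pve", "cumulative_f",
    "weak_instrument", "skip_reason",
]
COLOC_COLUMNS = [
    "tissue", "exposure", "outcome", "nsnps",
    "PP.H0", "PP.H1", "PP.H2", "PP.H3", "PP.H4", "call",
]
CONCORDANCE_COLUMNS = [
    "protein", "outcome", "tissues_significant", "directions", "classification",
]


def _mr_rows(records: list) -> list:
    rows = []
    for r in records:
        base = {
            "protein": r.protein, "tissue": r.tissue, "outcome": r.outcome,
            "family": r.family, "pfdr": r.pfdr, "significant": r.significant,
            "pve": r.pve, "cumulative_f": r.cumulative_f,
            "weak_instrument": r.weak_instrument, "skip_reason": r.skip_reason,
        }
        if not r.results:
            rows.append({**base, "method": "", "n_snps": 0})
            continue
        for method in sorted(r.results):
            res: MRResult = r.results[method]
            orr = res.or_scale or (None, None, None)
            rows.append({
                **base,
                "method": method, "n_snps": res.n_snps, "estimate": res.estimate,
                "se": res.se, "ci_low": res.ci_low, "ci_high": res.ci_high,
                "pvalue": res.pvalue, "Q": res.Q, "I2": res.I2,
                "odds_ratio": orr[0], "or_ci_low": orr[1], "or_ci_high": orr[2],
                # FDR annotation belongs to the primary estimator only
                "pfdr": r.pfdr if method == r.method else None,
                "significant": r.significant if method == r.method else None,
            })
    return rows


def render_reports(records: list, coloc_rows: list, concordance: list,
                   outdir, cfg: PipelineConfig) -> dict:
    """Write mr_results.tsv, coloc_results.tsv, concordance.tsv and a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "mr_results": outdir / "mr_results.tsv",
        "coloc_results": outdir / "coloc_results.tsv",
        "concordance": outdir / "concordance.tsv",
        "manifest": outdir / "manifest.json",
    }
    pd.DataFrame(_mr_rows(records), columns=MR_COLUMNS).to_csv(
        paths["mr_results"], sep="\t", index=False, float_format="%.10g"
    )
    coloc_df = pd.DataFrame(
        [
            {
                "tissue": c.tissue, "exposure": c.protein, "outcome": c.outcome,
                **c.result.as_dict(),
            }
            for c in coloc_rows
        ],
        columns=COLOC_COLUMNS,
    )
    coloc_df.to_csv(paths["coloc_results"], sep="\t", index=False, float_format="%.10g")
    pd.DataFrame(
        [
            {
                "protein": c.protein, "outcome": c.outcome,
                "tissues_significant": ",".join(c.tissues_significant),
                "directions": ",".join(str(d) for d in c.directions),
                "classification": c.classification,
            }
            for c in concordance
        ],
        columns=CONCORDANCE_COLUMNS,
    ).to_csv(paths["concordance"], sep="\t", index=False)

    echo = cfg.echo()
    config_hash = hashlib.sha256(
        json.dumps(echo, sort_keys=True).encode()
    ).hexdigest()
    manifest = {
        "package": "cismr",
        "version": __version__,
        "seed": cfg.seed,
        "config": echo,
        "config_sha256": config_hash,
        "counts": {
            "analyses": len(records),
            "skipped": sum(1 for r in records if r.skip_reason),
            "significant": sum(1 for r in records if r.significant),
            "coloc_tested": len(coloc_rows),
            "colocalized": sum(1 for c in coloc_rows if c.result.call == "colocalized"),
        },
        "files": sorted(p.name for k, p in paths.items() if k != "manifest"),
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return {k: str(v) for k, v in paths.items()}


def run_pipeline(cfg: PipelineConfig, outdir) -> dict:
    """Primary MR -> follow-up MR -> colocalization -> concordance -> reports."""
    primary = run_primary(cfg)
    followup = run_followup(primary, cfg)
    records = primary + followup
    coloc_rows = run_coloc_stage(records, cfg) if cfg.run_coloc else []
    concordance = classify_concordance(records)
    paths = render_reports(records, coloc_rows, concordance, outdir, cfg)
    return {
        "records": records,
        "coloc": coloc_rows,
        "concordance": concordance,
        "paths": paths,
    }
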