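"""Synthetic two-sample GWAS summary statistics with known truth.

Real cis-MR studies draw on external pQTL/eQTL and outcome GWAS datasets.
This module emulates their *statistical* structure so that every pipeline
stage can be exercised with ground truth in hand:

* standardized-genotype marginal model: for a locus with LD correlation
  matrix R and joint (causal) effects b, observed marginal effects are drawn
  as ``beta_hat ~ N(R b, (1 - pve) R / n)`` with per-variant
  ``se = sqrt((1 - pve)/n)`` — exactly the sufficient statistics a
  summary-level pipeline consumes, orders of magnitude cheaper than
  individual-level genotypes;
* exposure and outcome are simulated in two independent samples (two-sample
  design, no participant overlap);
* scenarios mirror the colocalization hypotheses: H0 (no signal), H1/H2
  (signal in one trait only), H3 (distinct causal variants, r^2 < 0.01
  enforced between them), H4_causal (outcome effect theta * b_exp at the
  shared variant), H4_shared_noncausal (shared variant, unrelated effect
  size), plus directional_pleiotropy (each instrument locus leaks a direct
  outcome effect with mean ``pleiotropy_intercept``);
* LD is AR(1): r[i][j] = rho^|i-j|, positive definite by construction;
* allele labels include a configurable fraction of palindromic (A/T, C/G)
  variants to exercise harmonisation; causal variants are kept
  non-palindromic so recovery experiments measure estimator error rather
  than harmonisation attrition.

Binary outcomes are approximated on the log-odds scale with effective sample
size ``4/(1/n_cases + 1/n_controls)``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from functools import lru_cache
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.linalg import block_diag, cholesky

from .harmonise import InstrumentSet, build_instrument_set
from .sumstats import (
    GeneRegion,
    LDMatrix,
    RegionData,
    TraitMeta,
    VariantAssoc,
    pvalue_from_z,
    write_ld_matrix,
    write_sumstats,
)

__all__ = [
    "ScenarioConfig",
    "TruthRecord",
    "make_ld",
    "rep_seeds",
    "simulate_region_pair",
    "simulate_instrument_catalogue",
    "simulate_study",
    "true_instrument_set",
    "locus_gene_region",
    "write_scenario",
    "SCENARIOS",
]


def rep_seeds(master_seed: int, n: int) -> list:
    """n statistically independent replicate seeds spawned from one master.

    Spawned :class:`numpy.random.SeedSequence` children avoid the stream
    correlations consecutive integer seeds could in principle induce, and give
    every experiment a single reproducibility handle.
    """
    ss = np.random.SeedSequence(master_seed)
    return [int(c.generate_state(1)[0] % (2**31 - 1)) for c in ss.spawn(n)]

SCENARIOS = (
    "H0",
    "H1",
    "H2",
    "H3",
    "H4_causal",
    "H4_shared_noncausal",
    "directional_pleiotropy",
)

NON_PALINDROMIC_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]
PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass(frozen=True)
class ScenarioConfig:
    """Conditions for one simulated locus pair or instrument catalogue."""

    scenario: str = "H4_causal"
    m_variants: int = 200
    ld_rho: float = 0.9
    maf_range: tuple = (0.05, 0.5)
    pve_exposure: float = 0.01
    theta: float = 0.3
    n_exp: int = 50_000
    n_out: int = 50_000
    n_instrument_loci: int = 10
    m_per_locus: int = 21
    pleiotropy_intercept: float = 0.0
    pleiotropy_sd: float = 0.02
    pve_spread: float = 0.5
    palindromic_frac: float = 0.10
    binary_outcome: bool = False
    n_cases: Optional[int] = None
    n_controls: Optional[int] = None
    seed: int = 0

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ValueError("ld_rho must lie in [0, 1)")
        if not (0.0 < self.pve_exposure < 1.0):
            raise ValueError("pve_exposure must lie in (0, 1)")
        if self.n_exp <= 10 or self.n_out <= 10:
            raise ValueError("sample sizes must exceed 10")
        if self.binary_outcome and not (self.n_cases and self.n_controls):
            raise ValueError("binary outcomes need n_cases and n_controls")
        if not (0.0 <= self.pve_spread < 1.0):
            raise ValueError("pve_spread must lie in [0, 1)")

    @property
    def n_out_effective(self) -> float:
        if self.binary_outcome:
            return 4.0 / (1.0 / self.n_cases + 1.0 / self.n_controls)
        return float(self.n_out)

    def outcome_meta(self, trait_id: str = "outcome_1") -> TraitMeta:
        if self.binary_outcome:
            return TraitMeta(
                trait_id, "binary", "none", "log-odds",
                n_cases=self.n_cases, n_controls=self.n_controls,
            )
        return TraitMeta(trait_id, "quantitative", "none", "SD")


@dataclass
class TruthRecord:
    """Ground truth behind one simulated dataset."""

    scenario: str
    causal_exposure_ids: list
    causal_outcome_ids: list
    theta: float
    pleiotropy_intercept: float
    b_exp_joint: list
    b_out_joint: list

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))


def make_ld(m: int, rho: float, ids: Optional[list] = None) -> LDMatrix:
    """AR(1) LD matrix r[i][j] = rho^|i-j| (positive definite for rho in [0,1))."""
    if not (0.0 <= rho < 1.0):
        raise ValueError("rho must lie in [0, 1)")
    idx = np.arange(m)
    r = rho ** np.abs(idx[:, None] - idx[None, :])
    return LDMatrix(ids or [f"v{i + 1}" for i in range(m)], r)


@lru_cache(maxsize=8)
def _cached_chol(m: int, rho: float) -> np.ndarray:
    idx = np.arange(m)
    r = rho ** np.abs(idx[:, None] - idx[None, :])
    return cholesky(r, lower=True)


def _draw_alleles(rng, m: int, frac_palindromic: float, protect: set) -> list:
    pairs = []
    for i in range(m):
        if i not in protect and rng.random() < frac_palindromic:
            pairs.append(PALINDROMIC_PAIRS[rng.integers(len(PALINDROMIC_PAIRS))])
        else:
            pairs.append(NON_PALINDROMIC_PAIRS[rng.integers(len(NON_PALINDROMIC_PAIRS))])
    return pairs


def _draw_eaf(rng, m: int, maf_range: tuple) -> np.ndarray:
    maf = rng.uniform(maf_range[0], maf_range[1], size=m)
    flip = rng.random(m) < 0.5
    return np.where(flip, 1.0 - maf, maf)


def _simulate_marginals(L: np.ndarray, b: np.ndarray, n: float, rng) -> tuple:
    """Marginal betas ~ N(R b, (1-pve) R / n) via the Cholesky factor L of R."""
    pve = float(b @ (L @ (L.T @ b)))  # b' R b
    resid = max(1.0 - pve, 1e-6)
    se = math.sqrt(resid / n)
    mean = L @ (L.T @ b)
    beta = mean + se * (L @ rng.standard_normal(len(b)))
    return beta, np.full(len(b), se)


def _assemble_region(meta, chrom, ids, positions, alleles, eaf, beta, se, n, ld):
    variants = [
        VariantAssoc(
            variant_id=ids[i],
            chrom=chrom[i] if isinstance(chrom, list) else chrom,
            pos=int(positions[i]),
            effect_allele=alleles[i][0],
            other_allele=alleles[i][1],
            beta=float(beta[i]),
            se=float(se[i]),
            eaf=float(eaf[i]),
            pvalue=pvalue_from_z(beta[i] / se[i]),
            n=int(n),
        )
        for i in range(len(ids))
    ]
    return RegionData(meta, variants, ld)


def _h3_separation(rho: float) -> int:
    """Smallest index distance d with r^2 = rho^(2d) < 0.01."""
    if rho == 0.0:
        return 1
    return int(math.floor(math.log(0.01) / (2.0 * math.log(rho)))) + 1


def locus_gene_region(cfg: ScenarioConfig, gene_id: str = "GENE1") -> GeneRegion:
    """A gene placed at the centre of the simulated locus (cis window covers it)."""
    centre = 1_100_000 + 2_500 * (cfg.m_variants // 2)
    return GeneRegion(gene_id, "1", max(1, centre - 5_000), centre + 5_000)


def simulate_region_pair(cfg: ScenarioConfig) -> tuple:
    """Simulate one cis locus for exposure and outcome in two samples.

    Returns (exposure RegionData, outcome RegionData, TruthRecord).  The two
    regions share variant ids, positions, allele labels and (noisy) allele
    frequencies; marginal effects are drawn independently per trait.
    """
    rng = np.random.default_rng(cfg.seed)
    m = cfg.m_variants
    ids = [f"rs{i + 1}" for i in range(m)]
    positions = 1_100_000 + 2_500 * np.arange(m)
    L = _cached_chol(m, cfg.ld_rho)

    exp_idx = m // 2
    b_exp = np.zeros(m)
    b_out = np.zeros(m)
    causal_exp, causal_out = [], []
    true_theta = 0.0
    beta_causal = math.sqrt(cfg.pve_exposure)

    if cfg.scenario in ("H1", "H3", "H4_causal", "H4_shared_noncausal", "directional_pleiotropy"):
        b_exp[exp_idx] = beta_causal
        causal_exp = [ids[exp_idx]]
    if cfg.scenario == "H2":
        b_out[exp_idx] = cfg.theta * beta_causal
        causal_out = [ids[exp_idx]]
    elif cfg.scenario == "H3":
        d = _h3_separation(cfg.ld_rho)
        out_idx = exp_idx + d
        if out_idx >= m:
            raise ValueError(
                f"H3 infeasible: m={m} too small for r^2<0.01 at rho={cfg.ld_rho} "
                f"(needs index distance {d})"
            )
        b_out[out_idx] = cfg.theta * beta_causal
        causal_out = [ids[out_idx]]
    elif cfg.scenario == "H4_causal":
        b_out = cfg.theta * b_exp
        causal_out = [ids[exp_idx]]
        true_theta = cfg.theta
    elif cfg.scenario == "H4_shared_noncausal":
        mag = cfg.theta * beta_causal * rng.uniform(0.5, 1.5)
        b_out[exp_idx] = mag * (1.0 if rng.random() < 0.5 else -1.0)
        causal_out = [ids[exp_idx]]
    elif cfg.scenario == "directional_pleiotropy":
        b_out = cfg.theta * b_exp
        b_out[exp_idx] += rng.normal(cfg.pleiotropy_intercept, cfg.pleiotropy_sd)
        causal_out = [ids[exp_idx]]
        true_theta = cfg.theta

    protect = {exp_idx}
    if causal_out:
        protect.add(ids.index(causal_out[0]))
    alleles = _draw_alleles(rng, m, cfg.palindromic_frac, protect)
    eaf = _draw_eaf(rng, m, cfg.maf_range)
    eaf_out = np.clip(eaf + rng.normal(0.0, 0.005, size=m), 0.005, 0.995)

    beta_e, se_e = _simulate_marginals(L, b_exp, cfg.n_exp, rng)
    beta_o, se_o = _simulate_marginals(L, b_out, cfg.n_out_effective, rng)

    ld = LDMatrix(ids, L @ L.T)
    exp_meta = TraitMeta("protein_1", "quantitative", "CSF", "log-RFU")
    n_out_reported = (
        cfg.n_cases + cfg.n_controls if cfg.binary_outcome else cfg.n_out
    )
    exposure = _assemble_region(
        exp_meta, "1", ids, positions, alleles, eaf, beta_e, se_e, cfg.n_exp, ld
    )
    outcome = _assemble_region(
        cfg.outcome_meta(), "1", ids, positions, alleles, eaf_out, beta_o, se_o,
        n_out_reported, None,
    )
    truth = TruthRecord(
        scenario=cfg.scenario,
        causal_exposure_ids=causal_exp,
        causal_outcome_ids=causal_out,
        theta=true_theta,
        pleiotropy_intercept=(
            cfg.pleiotropy_intercept if cfg.scenario == "directional_pleiotropy" else 0.0
        ),
        b_exp_joint=b_exp.tolist(),
        b_out_joint=b_out.tolist(),
    )
    return exposure, outcome, truth


def simulate_instrument_catalogue(cfg: ScenarioConfig) -> tuple:
    """Simulate several independent cis loci, one true instrument each.

    Loci live on distinct chromosome labels with block-diagonal LD, so
    clumping and harmonisation behave exactly as they would across a multi-
    locus catalogue.  Per-locus exposure variance explained is drawn uniform
    in ``pve_exposure * [1 - pve_spread, 1 + pve_spread]`` (instrument
    strengths must vary for the MR-Egger slope and intercept to be jointly
    identifiable).  Under ``directional_pleiotropy`` each locus adds a direct
    outcome effect alpha_l ~ N(pleiotropy_intercept, pleiotropy_sd) at the
    instrument, so the true Egger intercept equals ``pleiotropy_intercept``.
    """
    if cfg.n_instrument_loci < 2:
        raise ValueError("need at least 2 instrument loci")
    rng = np.random.default_rng(cfg.seed)
    mloc = cfg.m_per_locus
    L = _cached_chol(mloc, cfg.ld_rho)
    centre = mloc // 2

    all_ids, all_chrom, all_pos, all_alleles = [], [], [], []
    eafs, eafs_out = [], []
    be_list, bo_list, se_e_list, se_o_list = [], [], [], []
    causal_exp, causal_out = [], []
    b_exp_all, b_out_all = [], []
    blocks = []

    for l in range(cfg.n_instrument_loci):
        ids = [f"rs{l + 1}_{i + 1}" for i in range(mloc)]
        pve_l = cfg.pve_exposure * rng.uniform(1.0 - cfg.pve_spread, 1.0 + cfg.pve_spread)
        b_exp = np.zeros(mloc)
        b_exp[centre] = math.sqrt(pve_l)
        b_out = cfg.theta * b_exp
        if cfg.scenario == "directional_pleiotropy":
            b_out[centre] += rng.normal(cfg.pleiotropy_intercept, cfg.pleiotropy_sd)
        elif cfg.scenario in ("H0", "H1"):
            b_out = np.zeros(mloc)

        alleles = _draw_alleles(rng, mloc, cfg.palindromic_frac, {centre})
        eaf = _draw_eaf(rng, mloc, cfg.maf_range)
        eaf_o = np.clip(eaf + rng.normal(0.0, 0.005, size=mloc), 0.005, 0.995)
        beta_e, se_e = _simulate_marginals(L, b_exp, cfg.n_exp, rng)
        beta_o, se_o = _simulate_marginals(L, b_out, cfg.n_out_effective, rng)

        all_ids.extend(ids)
        all_chrom.extend([str(l + 1)] * mloc)
        all_pos.extend((1_000_000 + 2_500 * np.arange(mloc)).tolist())
        all_alleles.extend(alleles)
        eafs.append(eaf)
        eafs_out.append(eaf_o)
        be_list.append(beta_e)
        bo_list.append(beta_o)
        se_e_list.append(se_e)
        se_o_list.append(se_o)
        causal_exp.append(ids[centre])
        causal_out.append(ids[centre])
        b_exp_all.extend(b_exp.tolist())
        b_out_all.extend(b_out.tolist())
        blocks.append(L @ L.T)

    ld = LDMatrix(all_ids, block_diag(*blocks))
    exp_meta = TraitMeta("protein_1", "quantitative", "CSF", "log-RFU")
    n_out_reported = (
        cfg.n_cases + cfg.n_controls if cfg.binary_outcome else cfg.n_out
    )
    exposure = _assemble_region(
        exp_meta, all_chrom, all_ids, all_pos, all_alleles,
        np.concatenate(eafs), np.concatenate(be_list), np.concatenate(se_e_list),
        cfg.n_exp, ld,
    )
    outcome = _assemble_region(
        cfg.outcome_meta(), all_chrom, all_ids, all_pos, all_alleles,
        np.concatenate(eafs_out), np.concatenate(bo_list), np.concatenate(se_o_list),
        n_out_reported, None,
    )
    truth = TruthRecord(
        scenario=cfg.scenario,
        causal_exposure_ids=causal_exp,
        causal_outcome_ids=causal_out if cfg.scenario not in ("H0", "H1") else [],
        theta=cfg.theta if cfg.scenario not in ("H0", "H1") else 0.0,
        pleiotropy_intercept=(
            cfg.pleiotropy_intercept if cfg.scenario == "directional_pleiotropy" else 0.0
        ),
        b_exp_joint=b_exp_all,
        b_out_joint=b_out_all,
    )
    return exposure, outcome, truth


def simulate_study(
    cfg: ScenarioConfig,
    n_proteins: int = 5,
    outcome_ids: tuple = ("out1", "out2"),
    true_pairs: frozenset = frozenset({("protein_1", "out1")}),
    tissues: tuple = ("CSF",),
) -> dict:
    """Simulate a protein catalogue against several shared outcome GWASs.

    Each protein gets one cis locus (``m_per_locus`` variants on its own
    chromosome label); each outcome GWAS covers every locus.  One QTL dataset
    per requested tissue is drawn at the same locus with the same joint
    effects (an independent measurement sample per tissue).  Outcome effects
    are ``theta * b_exp`` for (protein, outcome) pairs in ``true_pairs`` and
    zero otherwise, drawn once per outcome with independent sampling noise,
    so the exposure datasets are shared across outcomes exactly as in a real
    study.

    Returns a dict with ``exposures`` (list of (protein, tissue, RegionData,
    GeneRegion)), ``outcomes`` (trait_id -> RegionData), and ``true_pairs``.
    """
    rng = np.random.default_rng(cfg.seed)
    mloc = cfg.m_per_locus
    L = _cached_chol(mloc, cfg.ld_rho)
    centre = mloc // 2
    positions = 1_000_000 + 2_500 * np.arange(mloc)

    exposures = []
    per_outcome: dict = {o: [] for o in outcome_ids}
    for p in range(n_proteins):
        protein = f"protein_{p + 1}"
        chrom = str(p + 1)
        ids = [f"p{p + 1}_v{i + 1}" for i in range(mloc)]
        pve_l = cfg.pve_exposure * rng.uniform(1.0 - cfg.pve_spread, 1.0 + cfg.pve_spread)
        b_exp = np.zeros(mloc)
        b_exp[centre] = math.sqrt(pve_l)
        alleles = _draw_alleles(rng, mloc, cfg.palindromic_frac, {centre})
        eaf = _draw_eaf(rng, mloc, cfg.maf_range)
        gene_centre = int(positions[centre])
        gene = GeneRegion(protein, chrom, max(1, gene_centre - 5_000), gene_centre + 5_000)
        for tissue in tissues:
            beta_e, se_e = _simulate_marginals(L, b_exp, cfg.n_exp, rng)
            meta = TraitMeta(protein, "quantitative", tissue, "log-RFU")
            region = _assemble_region(
                meta, chrom, ids, positions, alleles, eaf, beta_e, se_e,
                cfg.n_exp, LDMatrix(ids, L @ L.T),
            )
            exposures.append((protein, tissue, region, gene))
        eaf_o = np.clip(eaf + rng.normal(0.0, 0.005, size=mloc), 0.005, 0.995)
        for out_id in outcome_ids:
            b_out = cfg.theta * b_exp if (protein, out_id) in true_pairs else np.zeros(mloc)
            beta_o, se_o = _simulate_marginals(L, b_out, cfg.n_out_effective, rng)
            per_outcome[out_id].append(
                (chrom, ids, alleles, eaf_o, beta_o, se_o)
            )

    n_out_reported = cfg.n_cases + cfg.n_controls if cfg.binary_outcome else cfg.n_out
    outcomes = {}
    for out_id in outcome_ids:
        chroms, ids, alleles = [], [], []
        eafs, betas, ses = [], [], []
        pos_all = []
        for chrom, vids, alls, eaf_o, beta_o, se_o in per_outcome[out_id]:
            chroms.extend([chrom] * mloc)
            ids.extend(vids)
            alleles.extend(alls)
            eafs.append(eaf_o)
            betas.append(beta_o)
            ses.append(se_o)
            pos_all.extend(positions.tolist())
        outcomes[out_id] = _assemble_region(
            cfg.outcome_meta(out_id), chroms, ids, pos_all, alleles,
            np.concatenate(eafs), np.concatenate(betas), np.concatenate(ses),
            n_out_reported, None,
        )
    return {"exposures": exposures, "outcomes": outcomes, "true_pairs": set(true_pairs)}


def true_instrument_set(
    exposure: RegionData, outcome: RegionData, truth: TruthRecord
) -> InstrumentSet:
    """Harmonised instrument set built from the true causal variants."""
    by_id = exposure.by_id()
    instruments = [by_id[v] for v in truth.causal_exposure_ids]
    return build_instrument_set(instruments, outcome, exposure.trait)


def write_scenario(cfg: ScenarioConfig, outdir) -> dict:
    """Write exposure/outcome TSVs, the LD matrix, and the truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    exposure, outcome, truth = simulate_region_pair(cfg)
    paths = {
        "exposure": outdir / "exposure.tsv",
        "outcome": outdir / "outcome.tsv",
        "ld": outdir / "ld.tsv",
        "truth": outdir / "truth.json",
    }
    write_sumstats(exposure, paths["exposure"])
    write_sumstats(outcome, paths["outcome"])
    write_ld_matrix(exposure.ld, paths["ld"])
    truth.to_json(paths["truth"])
    return {k: str(v) for k, v in paths.items()}
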