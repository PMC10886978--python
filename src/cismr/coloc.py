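"""Single-causal-variant Bayesian colocalization.

Given full summary statistics for two traits over a shared locus, and
assuming at most one causal variant per trait within it, the locus is scored
under five hypotheses:

* H0 - no variant is associated with either trait;
* H1 / H2 - a causal variant for the first / second trait only;
* H3 - distinct causal variants for the two traits (association at the locus
  is confounded by LD);
* H4 - a single causal variant shared by both traits (colocalization).

Per-variant evidence is a Wakefield-style approximate Bayes factor computed
from beta and SE with a normal effect prior; hypothesis likelihoods combine
the ABFs with per-variant priors p1, p2, p12 and are normalized into
posterior probabilities PPH0..PPH4.  All sums run in log space, so loci with
|z| of several hundred remain finite.

Decision rules: PPH4 > 0.5 calls colocalization; PPH3 > 0.5 calls
confounding by LD (distinct causal variants).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .sumstats import RegionData, VariantAssoc

__all__ = ["ColocConfig", "ColocResult", "log_abf", "coloc_abf", "coloc_eligibility"]

#: below this many variants the single-causal-variant posteriors are
#: unreliable: full locus summary statistics, not instruments, are required
MIN_RELIABLE_SNPS = 25


@dataclass(frozen=True)
class ColocConfig:
    """Priors for the colocalization enumeration.

    p1, p2: prior probability that any one variant is causal for the first /
    second trait; p12: prior that it is causal for both.  Effect-size prior
    SDs: 0.20 for quantitative traits (per-SD scale), 0.15 on the log-odds
    scale for binary traits.
    """

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5
    prior_sd_quant: float = 0.20
    prior_sd_binary: float = 0.15

    def __post_init__(self):
        if not (0 < self.p12 <= min(self.p1, self.p2) < 1):
            raise ValueError("priors must satisfy 0 < p12 <= min(p1, p2) < 1")
        if self.prior_sd_quant <= 0 or self.prior_sd_binary <= 0:
            raise ValueError("prior effect SDs must be positive")

    def prior_sd_for(self, trait) -> float:
        return self.prior_sd_binary if trait.is_binary else self.prior_sd_quant


@dataclass(frozen=True)
class ColocResult:
    """Posterior probabilities over H0..H4 for one locus pair."""

    pph0: float
    pph1: float
    pph2: float
    pph3: float
    pph4: float
    n_snps: int

    def __post_init__(self):
        total = self.pph0 + self.pph1 + self.pph2 + self.pph3 + self.pph4
        if abs(total - 1.0) > 1e-10:
            raise ValueError(f"posteriors sum to {total}, not 1")

    @property
    def call(self) -> str:
        if self.pph4 > 0.5:
            return "colocalized"
        if self.pph3 > 0.5:
            return "confounded_by_LD"
        return "underpowered/other"

    def as_dict(self) -> dict:
        return {
            "nsnps": self.n_snps,
            "PP.H0": self.pph0,
            "PP.H1": self.pph1,
            "PP.H2": self.pph2,
            "PP.H3": self.pph3,
            "PP.H4": self.pph4,
            "call": self.call,
        }


def log_abf(v: VariantAssoc, prior_sd: float) -> float:
    """Log approximate Bayes factor for one variant.

    With V = se^2, W = prior_sd^2, shrinkage r = W/(V+W) and z = beta/se:
    log ABF = (log(1-r) + r*z^2)/2.  Positive values favour association;
    as se grows the ABF tends to 1 (log 0): no information, no evidence.
    """
    V = v.se**2
    W = prior_sd**2
    r = W / (V + W)
    z = v.beta / v.se
    return 0.5 * (math.log1p(-r) + r * z * z)


def _log_abf_vec(region: RegionData, prior_sd: float) -> np.ndarray:
    se = np.array([v.se for v in region.variants])
    beta = np.array([v.beta for v in region.variants])
    r = prior_sd**2 / (se**2 + prior_sd**2)
    z = beta / se
    return 0.5 * (np.log1p(-r) + r * z * z)


def coloc_abf(
    exposure_region: RegionData,
    outcome_region: RegionData,
    cfg: ColocConfig = ColocConfig(),
) -> ColocResult:
    """Enumerate H0..H4 over a harmonised, order-aligned locus pair.

    With per-variant Bayes factors B1_i, B2_i the unnormalized likelihoods are

        L0 = 1
        L1 = p1 * sum_i B1_i
        L2 = p2 * sum_i B2_i
        L3 = p1*p2 * (sum_i B1_i * sum_i B2_i - sum_i B1_i*B2_i)
        L4 = p12 * sum_i B1_i*B2_i

    (the H3 cross-term excludes the shared-variant diagonal, so a one-variant
    locus has PPH3 = 0 exactly).  Everything is evaluated with log-sum-exp.
    """
    if len(exposure_region) == 0:
        raise ValueError("empty variant intersection")
    if exposure_region.variant_ids != outcome_region.variant_ids:
        raise ValueError("regions must be intersected and order-aligned first")
    n = len(exposure_region)
    if n < MIN_RELIABLE_SNPS:
        warnings.warn(
            f"colocalization over {n} variants (<{MIN_RELIABLE_SNPS}): full locus "
            "summary statistics are required for reliable posteriors",
            UserWarning,
            stacklevel=2,
        )
    l1 = _log_abf_vec(exposure_region, cfg.prior_sd_for(exposure_region.trait))
    l2 = _log_abf_vec(outcome_region, cfg.prior_sd_for(outcome_region.trait))
    lsum1 = logsumexp(l1)
    lsum2 = logsumexp(l2)
    lsum12 = logsumexp(l1 + l2)
    logL = np.empty(5)
    logL[0] = 0.0
    logL[1] = math.log(cfg.p1) + lsum1
    logL[2] = math.log(cfg.p2) + lsum2
    # log(sum_{i!=j} B1_i B2_j) = log(exp(a) - exp(b)) with a >= b guaranteed
    # analytically; numerical ties (n = 1, or one dominant variant) give -inf
    a, b = lsum1 + lsum2, lsum12
    if b >= a:
        logL[3] = -np.inf
    else:
        logL[3] = math.log(cfg.p1) + math.log(cfg.p2) + a + math.log1p(-math.exp(b - a))
    logL[4] = math.log(cfg.p12) + lsum12
    post = np.exp(logL - logsumexp(logL))
    post /= post.sum()
    return ColocResult(*(float(p) for p in post), n_snps=n)


def coloc_eligibility(records: list) -> list:
    """Select (protein, outcome, tissue) triples to take into colocalization.

    A protein-outcome pair qualifies when it is significant (pFDR < 0.05) in
    *both* CSF and brain in the primary analysis, or when a follow-up
    (plasma or brain-expression) association for a primary-significant pair
    is itself significant at pFDR < 0.05.  Qualifying pairs are tested in
    every tissue in which they were significant.

    ``records`` are AssociationRecord-like objects with attributes
    ``protein``, ``outcome``, ``tissue``, ``significant`` and ``family``
    (family ``"primary"`` for CSF/brain, anything else for follow-ups).
    """
    primary_sig: dict = {}
    followup_sig: dict = {}
    for r in records:
        if not r.significant:
            continue
        key = (r.protein, r.outcome)
        if getattr(r, "family", "primary") == "primary":
            primary_sig.setdefault(key, set()).add(r.tissue)
        else:
            followup_sig.setdefault(key, set()).add(r.tissue)
    out = set()
    for key, tissues in primary_sig.items():
        protein, outcome = key
        if {"CSF", "brain"} <= tissues:
            out.add((protein, outcome, "CSF"))
            out.add((protein, outcome, "brain"))
        for ft in followup_sig.get(key, ()):
            out.add((protein, outcome, ft))
            for pt in tissues:
                out.add((protein, outcome, pt))
    return sorted(out)
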