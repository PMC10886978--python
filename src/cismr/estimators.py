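"""Two-sample MR estimators and heterogeneity diagnostics.

Implements the estimators used for cis-MR of molecular traits:

* Wald ratio for single-instrument analyses (first-order delta-method SE);
* multiplicative random-effects IVW (weighted regression through the origin
  with weights 1/se_out^2; SE inflated by max(1, sqrt(Q/(k-1))));
* MR-Egger (weighted regression with intercept; the intercept estimates
  directional pleiotropy under InSIDE; t-based p-values with k-2 df);
* weighted median (robust to up to 50% invalid instruments by weight;
  parametric-bootstrap SE);
* Cochran's Q and I^2 heterogeneity statistics.

Binary outcomes analysed on the log-odds scale can be re-expressed as odds
ratios via :func:`to_reporting_scale`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy import stats

from .harmonise import InstrumentSet, HarmonisedPair
from .sumstats import TraitMeta, pvalue_from_z

__all__ = [
    "MRResult",
    "wald_ratio",
    "ivw",
    "cochran_q_i2",
    "egger",
    "weighted_median",
    "to_reporting_scale",
    "fit_mr",
]

Z95 = stats.norm.ppf(0.975)


@dataclass(frozen=True)
class MRResult:
    """One MR estimate: effect per unit exposure, with 95% CI and p-value."""

    method: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snps: int
    Q: Optional[float] = None
    I2: Optional[float] = None
    or_scale: Optional[tuple] = None  # (OR, OR_low, OR_high) for binary outcomes

    def __post_init__(self):
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValueError("CI must bracket the estimate")
        if self.I2 is not None and not (0.0 <= self.I2 <= 100.0):
            raise ValueError("I2 must lie in [0, 100]")


def _result(method, estimate, se, pvalue, n_snps, crit=Z95, **kw) -> MRResult:
    return MRResult(
        method=method,
        estimate=float(estimate),
        se=float(se),
        ci_low=float(estimate - crit * se),
        ci_high=float(estimate + crit * se),
        pvalue=float(pvalue),
        n_snps=n_snps,
        **kw,
    )


def wald_ratio(pair: HarmonisedPair) -> MRResult:
    """Single-instrument Wald ratio beta_out/beta_exp.

    SE by the first-order delta method, se_out/|beta_exp|, which ignores the
    exposure SE; with strong instruments (F > 20) the second-order correction
    is negligible.
    """
    if pair.beta_exp == 0:
        raise ValueError("Wald ratio undefined for beta_exp = 0")
    estimate = pair.beta_out / pair.beta_exp
    se = pair.se_out / abs(pair.beta_exp)
    return _result("wald_ratio", estimate, se, pvalue_from_z(estimate / se), 1)


def _arrays(instr: InstrumentSet):
    bx = np.array([p.beta_exp for p in instr.pairs])
    by = np.array([p.beta_out for p in instr.pairs])
    sy = np.array([p.se_out for p in instr.pairs])
    return bx, by, sy


def ivw(instr: InstrumentSet) -> MRResult:
    """Multiplicative random-effects inverse-variance-weighted estimate.

    Weighted least squares of beta_out on beta_exp through the origin with
    weights 1/se_out^2.  The fixed-effect SE is inflated by
    max(1, sqrt(Q/(k-1))): heterogeneity widens the interval but the estimate
    can never be reported as more precise than under fixed effects.
    """
    if len(instr) < 2:
        raise ValueError("IVW requires >= 2 instruments; use wald_ratio")
    bx, by, sy = _arrays(instr)
    w = 1.0 / sy**2
    sxx = np.sum(w * bx**2)
    estimate = np.sum(w * bx * by) / sxx
    base_se = sxx**-0.5
    k = len(instr)
    Q = float(np.sum(w * (by - estimate * bx) ** 2))
    inflation = max(1.0, math.sqrt(Q / (k - 1)))
    se = base_se * inflation
    i2 = max(0.0, (Q - (k - 1)) / Q) * 100.0 if Q > 0 else 0.0
    return _result("ivw", estimate, se, pvalue_from_z(estimate / se), k, Q=Q, I2=i2)


def cochran_q_i2(instr: InstrumentSet, ivw_estimate: float) -> tuple:
    """Cochran's Q around a given IVW estimate and the derived I^2 (percent).

    Large Q relative to its k-1 degrees of freedom flags heterogeneity among
    per-variant ratio estimates, a possible signature of horizontal pleiotropy.
    """
    if len(instr) < 2:
        raise ValueError("heterogeneity needs >= 2 instruments")
    bx, by, sy = _arrays(instr)
    w = 1.0 / sy**2
    Q = float(np.sum(w * (by - ivw_estimate * bx) ** 2))
    k = len(instr)
    i2 = max(0.0, (Q - (k - 1)) / Q) * 100.0 if Q > 0 else 0.0
    return Q, i2


def egger(instr: InstrumentSet) -> tuple:
    """MR-Egger regression; returns (slope MRResult, intercept MRResult).

    Pairs are first oriented so every beta_exp is positive (both betas negated
    where needed), as required for the InSIDE-based reading of the intercept.
    Weighted least squares of beta_out on beta_exp with intercept, weights
    1/se_out^2; SEs use multiplicative inflation max(1, residual SE) and
    p-values come from the t distribution with k-2 df (the intercept test is
    anti-conservative under a normal reference at small k).
    """
    if len(instr) < 3:
        raise ValueError("MR-Egger requires >= 3 instruments")
    bx, by, sy = _arrays(instr)
    sign = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * sign, by * sign
    w = 1.0 / sy**2
    X = np.column_stack([np.ones_like(bx), bx])
    xtwx = X.T @ (w[:, None] * X)
    cov_base = np.linalg.inv(xtwx)
    coef = cov_base @ (X.T @ (w * by))
    resid = by - X @ coef
    k = len(instr)
    sigma2 = float(np.sum(w * resid**2) / (k - 2))
    inflation = max(1.0, math.sqrt(sigma2))
    ses = np.sqrt(np.diag(cov_base)) * inflation
    df = k - 2
    pvals = [2.0 * stats.t.sf(abs(c / s), df) for c, s in zip(coef, ses)]
    crit = stats.t.ppf(0.975, df)
    slope = _result("egger_slope", coef[1], ses[1], pvals[1], k, crit=crit)
    intercept = _result("egger_intercept", coef[0], ses[0], pvals[0], k, crit=crit)
    return slope, intercept


def _interp_weighted_median(theta: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(theta, kind="stable")
    th = theta[order]
    w = weights[order] / np.sum(weights)
    cum = np.cumsum(w)
    s = cum - w / 2.0
    if 0.5 <= s[0]:
        return float(th[0])
    if 0.5 >= s[-1]:
        return float(th[-1])
    return float(np.interp(0.5, s, th))


def weighted_median(
    instr: InstrumentSet, n_boot: int = 1000, seed: Optional[int] = None
) -> MRResult:
    """Weighted median of per-variant ratio estimates.

    Ratios theta_j = beta_out_j/beta_exp_j carry weights
    w_j = beta_exp_j^2/se_out_j^2 (inverse variance of theta_j to first
    order), normalized to sum to one.  The estimate interpolates the sorted
    ratios at cumulative weight 0.5; it is consistent when valid instruments
    carry more than half the total weight.  The SE is a seeded parametric
    bootstrap: beta_exp and beta_out are redrawn from normal(beta, se) and
    the median recomputed.
    """
    if len(instr) < 3:
        raise ValueError("weighted median requires >= 3 instruments")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100 for a stable bootstrap SE")
    if seed is None:
        raise ValueError("a bootstrap seed is required for reproducibility")
    bx, by, sy = _arrays(instr)
    sx = np.array([p.se_exp for p in instr.pairs])
    theta = by / bx
    w = bx**2 / sy**2
    estimate = _interp_weighted_median(theta, w)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bxb = rng.normal(bx, sx)
        byb = rng.normal(by, sy)
        ok = bxb != 0
        boots[b] = _interp_weighted_median(byb[ok] / bxb[ok], bxb[ok] ** 2 / sy[ok] ** 2)
    se = float(np.std(boots, ddof=1))
    p = pvalue_from_z(estimate / se) if se > 0 else (1.0 if estimate == 0 else 0.0)
    return _result("weighted_median", estimate, se, p, len(instr))


def to_reporting_scale(res: MRResult, outcome: TraitMeta) -> MRResult:
    """Attach the odds-ratio triple for binary outcomes; pass through otherwise."""
    if not outcome.is_binary:
        return res
    return replace(
        res,
        or_scale=(math.exp(res.estimate), math.exp(res.ci_low), math.exp(res.ci_high)),
    )


def fit_mr(
    instr: InstrumentSet, n_boot: int = 1000, seed: Optional[int] = None
) -> dict:
    """Dispatch the estimators appropriate to the instrument count.

    One instrument: Wald ratio only.  Two: IVW.  Three or more: IVW plus the
    MR-Egger and weighted-median sensitivity analyses.  Returns a dict keyed
    by method name, all on the outcome's reporting scale.
    """
    results = {}
    if len(instr) == 1:
        results["wald_ratio"] = wald_ratio(instr.pairs[0])
    else:
        results["ivw"] = ivw(instr)
        if len(instr) >= 3:
            slope, intercept = egger(instr)
            results["egger_slope"] = slope
            results["egger_intercept"] = intercept
            results["weighted_median"] = weighted_median(instr, n_boot=n_boot, seed=seed)
    return {k: to_reporting_scale(r, instr.outcome) for k, r in results.items()}
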