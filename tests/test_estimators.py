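"""MR estimators: closed-form cases, WLS oracles, robustness properties."""

import math

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

from cismr.estimators import (
    cochran_q_i2,
    egger,
    fit_mr,
    ivw,
    to_reporting_scale,
    wald_ratio,
    weighted_median,
)
from cismr.harmonise import HarmonisedPair
from cismr.sumstats import TraitMeta
from conftest import make_instrument_set


def random_instrument_set(seed, k_max=8):
    rng = np.random.default_rng(seed)
    k = int(rng.integers(3, k_max + 1))
    bx = rng.normal(0.1, 0.05, k)
    bx[bx == 0] = 0.01
    return make_instrument_set(
        bx=bx,
        by=rng.normal(0.03, 0.02, k),
        sy=rng.uniform(0.005, 0.05, k),
        sx=rng.uniform(0.002, 0.01, k),
    )


def ivw_oracle(instr):
    bx, by, sy = (np.array([getattr(p, a) for p in instr.pairs])
                  for a in ("beta_exp", "beta_out", "se_out"))
    fit = sm.WLS(by, bx, weights=1 / sy**2).fit()
    base = fit.bse[0] / math.sqrt(fit.scale)
    return fit.params[0], base * max(1.0, math.sqrt(fit.scale))


def egger_oracle(instr):
    bx, by, sy = (np.array([getattr(p, a) for p in instr.pairs])
                  for a in ("beta_exp", "beta_out", "se_out"))
    s = np.where(bx < 0, -1.0, 1.0)
    fit = sm.WLS(by * s, sm.add_constant(bx * s), weights=1 / sy**2).fit()
    base = fit.bse / np.sqrt(fit.scale)
    infl = max(1.0, math.sqrt(fit.scale))
    return fit.params, base * infl


def wm_oracle(theta, w):
    order = np.argsort(theta)
    th, ww = np.asarray(theta)[order], np.asarray(w)[order] / np.sum(w)
    s = np.cumsum(ww) - ww / 2
    if 0.5 <= s[0]:
        return th[0]
    if 0.5 >= s[-1]:
        return th[-1]
    for j in range(1, len(th)):
        if s[j] >= 0.5:
            return th[j - 1] + (0.5 - s[j - 1]) / (s[j] - s[j - 1]) * (th[j] - th[j - 1])


class TestWaldRatio:
    def pair(self, bx=0.5, by=0.25, sy=0.1):
        return HarmonisedPair("v1", bx, 0.05, by, sy, 0.3, 0.3, "aligned")

    def test_direct_formula(self):
        r = wald_ratio(self.pair())
        assert r.estimate == pytest.approx(0.5) and r.se == pytest.approx(0.2)

    def test_null_outcome(self):
        r = wald_ratio(self.pair(by=0.0))
        assert r.estimate == 0.0 and r.pvalue == pytest.approx(1.0)

    def test_pvalue_normal_approximation(self):
        r = wald_ratio(self.pair())
        assert r.pvalue == pytest.approx(2 * stats.norm.sf(2.5), rel=1e-9)

    def test_negative_exposure_beta(self):
        r = wald_ratio(self.pair(bx=-0.5))
        assert r.estimate == pytest.approx(-0.5) and r.se == pytest.approx(0.2)

    def test_zero_exposure_beta_rejected(self):
        with pytest.raises(ValueError):
            wald_ratio(self.pair(bx=0.0))


class TestIVW:
    def test_two_pair_closed_form(self):
        instr = make_instrument_set(bx=[1, 1], by=[0.2, 0.4], sy=[1, 1])
        r = ivw(instr)
        assert r.estimate == pytest.approx(0.3)
        assert r.Q == pytest.approx(0.02)
        assert r.se == pytest.approx(math.sqrt(0.5), rel=1e-9)  # inflation floored at 1

    def test_identical_pairs_zero_heterogeneity(self):
        instr = make_instrument_set(bx=[1] * 4, by=[0.3] * 4, sy=[1] * 4)
        r = ivw(instr)
        assert r.estimate == pytest.approx(0.3)
        assert r.Q == pytest.approx(0.0, abs=1e-12) and r.I2 == 0.0

    def test_single_pair_rejected(self):
        instr = make_instrument_set(bx=[1, 1], by=[0.1, 0.2], sy=[1, 1])
        instr.pairs = instr.pairs[:1]
        with pytest.raises(ValueError, match="wald_ratio"):
            ivw(instr)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_wls_oracle(self, seed):
        instr = random_instrument_set(seed)
        est, se = ivw_oracle(instr)
        r = ivw(instr)
        assert r.estimate == pytest.approx(est, abs=1e-10)
        assert r.se == pytest.approx(se, abs=1e-10)


class TestHeterogeneity:
    def test_i2_from_inflated_q(self):
        instr = make_instrument_set(bx=[1, 1], by=[math.sqrt(2), -math.sqrt(2)], sy=[1, 1])
        Q, i2 = cochran_q_i2(instr, 0.0)
        assert Q == pytest.approx(4.0) and i2 == pytest.approx(75.0)

    def test_i2_clipped_at_zero(self):
        instr = make_instrument_set(bx=[1, 1], by=[0.2, 0.4], sy=[1, 1])
        Q, i2 = cochran_q_i2(instr, 0.3)
        assert Q == pytest.approx(0.02) and i2 == 0.0

    def test_identical_ratios_give_zero(self):
        instr = make_instrument_set(bx=[1, 2, 3], by=[0.3, 0.6, 0.9], sy=[1, 1, 1])
        Q, i2 = cochran_q_i2(instr, 0.3)
        assert Q == pytest.approx(0.0, abs=1e-12) and i2 == 0.0


class TestEgger:
    def test_perfect_proportional_fit(self):
        instr = make_instrument_set(bx=[1, 2, 3], by=[1, 2, 3], sy=[1, 1, 1])
        slope, intercept = egger(instr)
        assert slope.estimate == pytest.approx(1.0)
        assert intercept.estimate == pytest.approx(0.0, abs=1e-12)

    def test_exact_intercept_recovery(self):
        bx = np.array([1.0, 2.0, 3.0, 4.0])
        instr = make_instrument_set(bx=bx, by=0.5 + 0.2 * bx, sy=[1] * 4)
        slope, intercept = egger(instr)
        assert slope.estimate == pytest.approx(0.2)
        assert intercept.estimate == pytest.approx(0.5)

    def test_orientation_invariance(self):
        """Negating an exposure beta (and its outcome beta) changes nothing."""
        instr = random_instrument_set(3)
        flipped = make_instrument_set(
            bx=[-p.beta_exp if i == 0 else p.beta_exp for i, p in enumerate(instr.pairs)],
            by=[-p.beta_out if i == 0 else p.beta_out for i, p in enumerate(instr.pairs)],
            sy=[p.se_out for p in instr.pairs],
            sx=[p.se_exp for p in instr.pairs],
        )
        s1, i1 = egger(instr)
        s2, i2 = egger(flipped)
        assert s1.estimate == pytest.approx(s2.estimate, abs=1e-12)
        assert i1.estimate == pytest.approx(i2.estimate, abs=1e-12)

    def test_pvalues_use_t_distribution(self):
        instr = random_instrument_set(5)
        slope, _ = egger(instr)
        k = len(instr)
        expected = 2 * stats.t.sf(abs(slope.estimate / slope.se), k - 2)
        assert slope.pvalue == pytest.approx(expected, rel=1e-9)

    def test_fewer_than_three_rejected(self):
        instr = make_instrument_set(bx=[1, 1], by=[0.1, 0.2], sy=[1, 1])
        with pytest.raises(ValueError):
            egger(instr)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_wls_oracle(self, seed):
        instr = random_instrument_set(seed + 100)
        coef, ses = egger_oracle(instr)
        slope, intercept = egger(instr)
        assert intercept.estimate == pytest.approx(coef[0], abs=1e-10)
        assert slope.estimate == pytest.approx(coef[1], abs=1e-10)
        assert intercept.se == pytest.approx(ses[0], abs=1e-10)
        assert slope.se == pytest.approx(ses[1], abs=1e-10)


class TestWeightedMedian:
    def test_equal_weights_symmetric_ratios(self):
        instr = make_instrument_set(bx=[1, 1, 1], by=[1, 2, 3], sy=[1, 1, 1])
        r = weighted_median(instr, n_boot=100, seed=1)
        assert r.estimate == pytest.approx(2.0)

    def test_interpolation_with_unequal_weights(self):
        # weights proportional to (2, 1, 1) -> normalized (0.5, 0.25, 0.25)
        s2 = math.sqrt(2.0)
        instr = make_instrument_set(bx=[s2, 1, 1], by=[s2, 2, 3], sy=[1, 1, 1])
        r = weighted_median(instr, n_boot=100, seed=1)
        assert r.estimate == pytest.approx(1 + (0.5 - 0.25) / (0.625 - 0.25), rel=1e-9)

    def test_degenerate_identical_ratios(self):
        instr = make_instrument_set(bx=[1, 2, 3], by=[0.4, 0.8, 1.2],
                                    sy=[1e-6] * 3, sx=[1e-9] * 3)
        r = weighted_median(instr, n_boot=100, seed=1)
        assert r.estimate == pytest.approx(0.4)
        assert r.se < 1e-4

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_interpolation_oracle_and_range(self, seed):
        instr = random_instrument_set(seed + 200)
        bx, by, sy = (np.array([getattr(p, a) for p in instr.pairs])
                      for a in ("beta_exp", "beta_out", "se_out"))
        theta = by / bx
        r = weighted_median(instr, n_boot=100, seed=2)
        assert r.estimate == pytest.approx(wm_oracle(theta, bx**2 / sy**2), abs=1e-12)
        assert min(theta) <= r.estimate <= max(theta)

    def test_bootstrap_reproducible_under_seed(self):
        instr = random_instrument_set(9)
        r1 = weighted_median(instr, n_boot=200, seed=42)
        r2 = weighted_median(instr, n_boot=200, seed=42)
        assert r1.se == r2.se

    def test_guards(self):
        instr = random_instrument_set(1)
        with pytest.raises(ValueError, match="seed"):
            weighted_median(instr, n_boot=200, seed=None)
        with pytest.raises(ValueError, match="n_boot"):
            weighted_median(instr, n_boot=50, seed=1)


class TestScalesAndDispatch:
    def test_binary_outcome_gets_odds_ratios(self):
        from dataclasses import replace

        instr = make_instrument_set(bx=[1, 1], by=[0.1, 0.2], sy=[1, 1], binary=True)
        base = replace(ivw(instr), estimate=-0.8, ci_low=-1.17, ci_high=-0.43)
        res = to_reporting_scale(base, instr.outcome)
        orr, lo, hi = res.or_scale
        assert (round(orr, 2), round(lo, 2), round(hi, 2)) == (0.45, 0.31, 0.65)

    def test_null_estimate_maps_to_unit_odds(self):
        instr = make_instrument_set(bx=[1, 1], by=[0, 0], sy=[1, 1], binary=True)
        res = to_reporting_scale(ivw(instr), instr.outcome)
        assert res.or_scale[0] == pytest.approx(1.0)

    def test_quantitative_outcome_untouched(self):
        instr = make_instrument_set(bx=[1, 1], by=[0.1, 0.2], sy=[1, 1])
        res = to_reporting_scale(ivw(instr), instr.outcome)
        assert res.or_scale is None

    def test_dispatch_by_instrument_count(self):
        one = make_instrument_set(bx=[1, 1], by=[0.1, 0.2], sy=[1, 1])
        one.pairs = one.pairs[:1]
        assert set(fit_mr(one, seed=1)) == {"wald_ratio"}
        two = make_instrument_set(bx=[1, 1], by=[0.1, 0.2], sy=[1, 1])
        assert set(fit_mr(two, seed=1)) == {"ivw"}
        three = make_instrument_set(bx=[1, 2, 3], by=[0.1, 0.2, 0.3], sy=[1, 1, 1])
        assert set(fit_mr(three, seed=1)) == {
            "ivw", "egger_slope", "egger_intercept", "weighted_median"
        }

    @pytest.mark.parametrize("c", [0.5, 2.0, 10.0])
    def test_scale_equivariance(self, c):
        """Rescaling the exposure by c > 0 divides every estimate by c."""
        instr = random_instrument_set(11)
        scaled = make_instrument_set(
            bx=[p.beta_exp * c for p in instr.pairs],
            by=[p.beta_out for p in instr.pairs],
            sy=[p.se_out for p in instr.pairs],
            sx=[p.se_exp * c for p in instr.pairs],
        )
        base = fit_mr(instr, n_boot=200, seed=3)
        got = fit_mr(scaled, n_boot=200, seed=3)
        for method in ("ivw", "egger_slope", "weighted_median"):
            assert got[method].estimate == pytest.approx(
                base[method].estimate / c, rel=1e-9
            )
        # the pleiotropy intercept is on the outcome scale: unchanged
        assert got["egger_intercept"].estimate == pytest.approx(
            base["egger_intercept"].estimate, rel=1e-9
        )
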