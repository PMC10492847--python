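import math

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from ivmr.errors import DomainError, InsufficientInstrumentsError
from ivmr.estimators import (egger, estimate_all, ivw, mode_estimate,
                             to_odds_ratio, wald_ratio, weighted_median)
from ivmr.harmonize import HarmonizedPair, HarmonizedSet
from ivmr.simulate import SimulationConfig, simulate_study, with_seed

from conftest import random_harmonized


def _set(rows):
    return HarmonizedSet("e", "o", [HarmonizedPair(f"rs{i}", *r)
                                    for i, r in enumerate(rows)])


class TestWaldRatio:
    def test_zero_outcome_effect(self):
        r, _ = wald_ratio(HarmonizedPair("x", 0.1, 0.01, 0.0, 0.02))
        assert r == 0.0

    def test_direct_substitution(self):
        r, se = wald_ratio(HarmonizedPair("x", 0.1, 0.01, 0.1, 0.02))
        assert (r, se) == (1.0, pytest.approx(0.2))

    def test_zero_exposure_effect_is_domain_error(self):
        with pytest.raises(DomainError):
            wald_ratio(HarmonizedPair("x", 0.0, 0.01, 0.1, 0.02))

    def test_second_order_se_never_smaller(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            p = HarmonizedPair("x", rng.uniform(0.01, 1), rng.uniform(0.001, 0.1),
                               rng.normal(), rng.uniform(0.001, 0.1))
            assert wald_ratio(p, "second")[1] >= wald_ratio(p, "first")[1]


class TestIVW:
    def test_toy_set_hand_values(self, toy_pairs):
        est = ivw(toy_pairs)
        assert est.beta == pytest.approx(0.11667, abs=1e-5)
        assert est.se == pytest.approx(0.04082, abs=1e-5)

    def test_equal_ratios_degenerate(self):
        hs = _set([(0.1, 0.01, 0.05, 0.02), (0.2, 0.01, 0.10, 0.02),
                   (0.4, 0.01, 0.20, 0.02)])
        est = ivw(hs)
        assert est.beta == pytest.approx(0.5)
        assert est.extra["cochran_q"] == pytest.approx(0.0, abs=1e-20)

    def test_point_estimate_identical_fixed_vs_random(self, toy_pairs):
        assert ivw(toy_pairs, "fixed").beta == ivw(toy_pairs, "random").beta
        assert ivw(toy_pairs, "random").se >= ivw(toy_pairs, "fixed").se

    def test_equals_wls_through_origin_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            hs = random_harmonized(rng, k=int(rng.integers(3, 30)))
            bx, sx, by, sy = hs.arrays()
            fit = sm.WLS(by, bx[:, None], weights=1 / sy**2).fit()
            est = ivw(hs)
            assert est.beta == pytest.approx(fit.params[0], rel=1e-10)

    def test_insufficient_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            ivw(_set([(0.1, 0.01, 0.05, 0.02)]))

    def test_sign_flip_equivariance(self, toy_pairs):
        flipped = HarmonizedSet("e", "o", [
            HarmonizedPair(p.rsid, -p.beta_exp, p.se_exp, -p.beta_out, p.se_out)
            if i % 2 else p for i, p in enumerate(toy_pairs.pairs)])
        assert ivw(flipped).beta == pytest.approx(ivw(toy_pairs).beta)


class TestEgger:
    def test_exact_line(self):
        hs = _set([(x, 0.01, 0.5 * x, 0.02) for x in (0.1, 0.2, 0.3, 0.4)])
        res = egger(hs)
        assert res.slope.beta == pytest.approx(0.5)
        assert res.intercept == pytest.approx(0.0, abs=1e-12)

    def test_normal_equations_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            hs = random_harmonized(rng, k=int(rng.integers(4, 25)))
            bx, sx, by, sy = hs.arrays()
            s = np.sign(bx)
            x, y, w = bx * s, by * s, 1 / sy**2
            # closed-form weighted normal equations
            sw, swx, swy = w.sum(), (w * x).sum(), (w * y).sum()
            swxx, swxy = (w * x * x).sum(), (w * x * y).sum()
            det = sw * swxx - swx**2
            slope = (sw * swxy - swx * swy) / det
            intercept = (swxx * swy - swx * swxy) / det
            res = egger(hs)
            assert res.slope.beta == pytest.approx(slope, rel=1e-10)
            assert res.intercept == pytest.approx(intercept, rel=1e-8, abs=1e-12)

    def test_slope_equals_ivw_when_intercept_constrained(self):
        # constraining the Egger intercept to zero is exactly IVW
        rng = np.random.default_rng(8)
        for _ in range(20):
            hs = random_harmonized(rng, k=12)
            bx, sx, by, sy = hs.arrays()
            s = np.sign(bx)
            fit = sm.WLS(by * s, (bx * s)[:, None], weights=1 / sy**2).fit()
            assert ivw(hs).beta == pytest.approx(fit.params[0], rel=1e-10)

    def test_degenerate_regressor(self):
        hs = _set([(0.1, 0.01, 0.05, 0.02)] * 4)
        with pytest.raises(DomainError):
            egger(hs)

    def test_insufficient_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            egger(_set([(0.1, 0.01, 0.05, 0.02), (0.2, 0.01, 0.1, 0.02)]))


class TestWeightedMedian:
    def test_exact_median_equal_weights(self):
        hs = _set([(1.0, 0.1, r, 0.1) for r in (0.1, 0.2, 0.3)])
        est = weighted_median(hs, weights="simple", n_boot=50, seed=1)
        assert est.beta == pytest.approx(0.2)

    def test_robust_to_single_outlier(self):
        rng = np.random.default_rng(5)
        rows = [(1.0, 0.02, rng.normal(0.1, 0.005), 0.02) for _ in range(9)]
        rows.append((1.0, 0.02, 5.0, 0.02))  # wild outlier
        est = weighted_median(_set(rows), n_boot=100, seed=2)
        assert 0.05 < est.beta < 0.15  # stays in the consistent cluster

    def test_duplicate_snp_with_half_weight_invariant(self):
        # duplicating a SNP while halving its weight leaves the weighted
        # median unchanged; exact whenever the duplicated ratio is not
        # adjacent to the crossing interval (the interpolation is local),
        # so duplicate the extreme ratio
        from ivmr.estimators import _weighted_median
        rng = np.random.default_rng(9)
        for _ in range(50):
            r = rng.normal(size=7)
            w = rng.uniform(0.5, 2.0, size=7)
            m = int(np.argmax(r))
            r2 = np.concatenate([r, [r[m]]])
            w2 = w.copy()
            w2[m] /= 2
            w2 = np.concatenate([w2, [w[m] / 2]])
            assert _weighted_median(r, w) == pytest.approx(
                _weighted_median(r2, w2), rel=1e-12)

    def test_bootstrap_se_reproducible(self, toy_pairs):
        a = weighted_median(toy_pairs, n_boot=200, seed=3)
        b = weighted_median(toy_pairs, n_boot=200, seed=3)
        assert a.se == b.se


class TestModeEstimate:
    def test_degenerate_identical_ratios(self):
        hs = _set([(1.0, 0.05, 0.25, 0.05)] * 5)
        est = mode_estimate(hs, n_boot=20, seed=4)
        assert est.beta == pytest.approx(0.25)

    def test_majority_mode_recovered(self):
        rng = np.random.default_rng(6)
        rows = [(1.0, 0.01, float(rng.normal(0.1, 0.01)), 0.01) for _ in range(7)]
        rows += [(1.0, 0.01, float(rng.normal(0.9, 0.01)), 0.01) for _ in range(3)]
        est = mode_estimate(_set(rows), weighted=False, n_boot=50, seed=5)
        # grid-search oracle at fine resolution over the same kernel density
        from ivmr.estimators import _kde_mode, _mode_bandwidth, _ratio_arrays
        r, se_r = _ratio_arrays(_set(rows))
        w = np.ones_like(r) / len(r)
        h = _mode_bandwidth(r, 1.0)
        grid = np.linspace(r.min() - h, r.max() + h, 200_001)
        from scipy import stats as sps
        dens = (w * sps.norm.pdf((grid[:, None] - r) / h)).sum(axis=1)
        oracle = grid[np.argmax(dens)]
        assert abs(est.beta - oracle) < 1e-3
        assert abs(est.beta - 0.1) < 0.05  # majority cluster wins


class TestToOddsRatio:
    def test_null_beta(self):
        orr = to_odds_ratio(0.0, 0.1)
        assert orr.or_ == 1.0
        assert orr.ci_low * orr.ci_high == pytest.approx(1.0)
        assert orr.pvalue == pytest.approx(1.0)

    def test_reconstructs_internally_consistent_ci(self):
        orr = to_odds_ratio(0.1215, 0.0398)
        assert orr.or_ == pytest.approx(1.1292, abs=2e-4)
        assert orr.ci_low == pytest.approx(1.0444, abs=2e-4)
        assert orr.ci_high == pytest.approx(1.2209, abs=2e-4)

    @given(st.floats(0.01, 3.0), st.floats(0.01, 3.0))
    @settings(max_examples=50, deadline=None)
    def test_p_decreasing_in_z(self, beta, se):
        p1 = to_odds_ratio(beta, se).pvalue
        p2 = to_odds_ratio(beta * 1.5, se).pvalue
        assert p2 <= p1

    def test_nonpositive_se_rejected(self):
        with pytest.raises(DomainError):
            to_odds_ratio(0.1, 0.0)


class TestParameterRecovery:
    def test_ivw_ci_coverage_on_simulated_instruments(self):
        # moderate replicate count here; the full 500-replicate check
        # lives in the acceptance suite
        theta = 0.12
        cfg = SimulationConfig(k=44, theta=theta, seed=0)
        hits = 0
        n = 150
        for s in range(n):
            study = simulate_study(with_seed(cfg, 10_000 + s))
            est = ivw(study.harmonized_truth())
            hits += est.ci_low <= theta <= est.ci_high
        assert 0.90 <= hits / n <= 0.99

    def test_estimate_all_methods_concordant_under_no_pleiotropy(self):
        study = simulate_study(SimulationConfig(k=44, theta=0.12, seed=77))
        res = estimate_all(study.harmonized_truth(), n_boot=100, seed=1)
        betas = [e.beta for e in res.estimates.values()]
        assert max(betas) - min(betas) < 0.05
        assert set(res.estimates) == {"ivw", "egger", "weighted_median",
                                      "simple_mode", "weighted_mode"}
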