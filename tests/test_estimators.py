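import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mrkit as mk
from mrkit.estimators import EstimationError, UnitError, _weighted_median

from conftest import make_hset, random_hset


class TestIVW:
    def test_single_iv_is_wald_ratio(self):
        h = make_hset([0.1], [0.01], [0.05], [0.01])
        est = mk.ivw_estimate(h, model="fixed")
        assert est.theta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.1)

    def test_three_iv_fixture(self, three_iv_hset):
        est = mk.ivw_estimate(three_iv_hset, model="fixed")
        assert est.theta == pytest.approx(140 / 300, rel=1e-12)
        assert est.se == pytest.approx(1 / np.sqrt(300), rel=1e-12)
        assert est.ci_low < est.theta < est.ci_high

    def test_null_numerator(self):
        h = make_hset([0.1, 0.2], [0.01] * 2, [0.0, 0.0], [0.01] * 2)
        assert mk.ivw_estimate(h, model="fixed").theta == 0.0

    def test_all_zero_exposure_effects_error(self):
        h = make_hset([0.0, 0.0], [0.01] * 2, [0.1, 0.1], [0.01] * 2)
        with pytest.raises(EstimationError):
            mk.ivw_estimate(h, model="fixed")

    def test_random_effects_never_narrower_than_fixed(self, rng):
        h = random_hset(rng, 15)
        fixed = mk.ivw_estimate(h, model="fixed")
        rand = mk.ivw_estimate(h, model="multiplicative_random")
        assert rand.theta == fixed.theta
        assert rand.se >= fixed.se

    def test_matches_brute_force_wls_through_origin(self, rng):
        for _ in range(20):
            h = random_hset(rng, int(rng.integers(3, 25)))
            bx, _sx, by, sy = h.arrays()
            ref = np.linalg.lstsq((bx / sy)[:, None], by / sy, rcond=None)[0][0]
            est = mk.ivw_estimate(h, model="fixed")
            assert est.theta == pytest.approx(ref, rel=1e-10)


class TestCochranQ:
    def test_perfectly_proportional_is_zero(self):
        h = make_hset([0.1, 0.2, 0.3], [0.01] * 3, [0.05, 0.1, 0.15], [0.01] * 3)
        q, df = mk.cochran_q(h, 0.5)
        assert q == pytest.approx(0.0, abs=1e-20)
        assert df == 2

    def test_three_iv_fixture_value(self, three_iv_hset):
        q, df = mk.cochran_q(three_iv_hset, 140 / 300)
        assert q == pytest.approx(2 / 3, rel=1e-9)
        assert df == 2

    def test_order_invariance(self, rng):
        h = random_hset(rng, 8)
        q1, _ = mk.cochran_q(h, 0.3)
        perm = list(rng.permutation(8))
        q2, _ = mk.cochran_q(h.subset(perm), 0.3)
        assert q1 == pytest.approx(q2, rel=1e-12)


class TestEgger:
    def test_exact_linear_data(self):
        bx = np.array([0.05, 0.1, 0.2, 0.15])
        by = 0.003 + 0.4 * bx
        h = make_hset(bx, [0.01] * 4, by, [0.01] * 4)
        est = mk.egger_estimate(h)
        assert est.theta == pytest.approx(0.4, abs=1e-10)
        assert est.extras["egger_intercept"] == pytest.approx(0.003, abs=1e-10)
        assert est.extras["intercept_pval"] > 0.05

    def test_three_iv_fixture(self, three_iv_hset):
        est = mk.egger_estimate(three_iv_hset)
        assert est.theta == pytest.approx(0.400, abs=1e-9)
        assert est.extras["egger_intercept"] == pytest.approx(0.00571, abs=1e-5)

    def test_orientation_invariance(self, three_iv_hset):
        est0 = mk.egger_estimate(three_iv_hset)
        flipped = make_hset([-0.10, 0.20, 0.05], [0.01] * 3,
                            [-0.05, 0.08, 0.025], [0.01, 0.02, 0.005])
        est1 = mk.egger_estimate(flipped)
        assert est1.theta == pytest.approx(est0.theta, rel=1e-12)
        assert est1.extras["egger_intercept"] == pytest.approx(
            est0.extras["egger_intercept"], rel=1e-12)

    def test_collinear_exposure_error(self):
        h = make_hset([0.1, 0.1, 0.1], [0.01] * 3, [0.02, 0.03, 0.04], [0.01] * 3)
        with pytest.raises(EstimationError, match="collinear"):
            mk.egger_estimate(h)


class TestWeightedMedian:
    def test_equal_weight_interpolation(self):
        assert _weighted_median(np.array([0.4, 0.5, 0.5]), np.ones(3)) == pytest.approx(0.5)

    def test_three_iv_fixture(self, three_iv_hset):
        est = mk.weighted_median_estimate(three_iv_hset, n_boot=200, seed=1)
        assert est.theta == pytest.approx(0.5, abs=1e-12)
        assert est.se > 0

    def test_constant_ratios(self):
        h = make_hset([0.1, 0.2, 0.4], [0.001] * 3, [0.03, 0.06, 0.12], [0.01] * 3)
        est = mk.weighted_median_estimate(h, n_boot=300, seed=2)
        assert est.theta == pytest.approx(0.3, abs=1e-12)

    def test_dominant_weight_limit(self):
        ratios = np.array([0.9, 0.1, 0.2, 0.3])
        w = np.array([1e6, 1.0, 1.0, 1.0])
        assert _weighted_median(ratios, w) == pytest.approx(0.9, abs=1e-3)

    def test_bit_reproducible(self, three_iv_hset):
        a = mk.weighted_median_estimate(three_iv_hset, n_boot=100, seed=7)
        b = mk.weighted_median_estimate(three_iv_hset, n_boot=100, seed=7)
        assert a.se == b.se


class TestModeBased:
    def test_point_mass(self):
        h = make_hset([0.1, 0.2, 0.4], [0.001] * 3, [0.05, 0.1, 0.2], [0.01] * 3)
        est = mk.mode_based_estimate(h, n_boot=50, seed=1)
        assert est.theta == pytest.approx(0.5, abs=1e-12)

    def test_majority_cluster_wins(self, rng):
        ratios = np.array([0.49, 0.5, 0.5, 0.51, 0.505, 1.5, 1.49])
        bx = np.full(7, 0.1)
        by = ratios * bx
        h = make_hset(bx, [0.001] * 7, by, [0.01] * 7)
        est = mk.mode_based_estimate(h, n_boot=50, seed=3)
        assert 0.45 <= est.theta <= 0.55

    def test_permutation_invariance(self, rng):
        h = random_hset(rng, 9)
        a = mk.mode_based_estimate(h, n_boot=10, seed=4)
        b = mk.mode_based_estimate(h.subset(list(rng.permutation(9))), n_boot=10, seed=4)
        assert a.theta == pytest.approx(b.theta, abs=1e-9)


class TestRobust:
    def test_clean_data_matches_ivw(self):
        h = make_hset([0.1, 0.2, 0.3], [0.01] * 3, [0.05, 0.1, 0.15], [0.01] * 3)
        ivw = mk.ivw_estimate(h, model="fixed")
        rob = mk.robust_ivw_estimate(h)
        assert rob.theta == pytest.approx(ivw.theta, abs=1e-8)

    def test_downweights_gross_outlier(self, three_iv_hset):
        bx = [0.10, 0.20, 0.05, 0.1]
        sx = [0.01] * 4
        by = [0.05, 0.08, 0.025, 0.5]  # last IV wildly off the ratio ~0.5
        sy = [0.01, 0.02, 0.005, 0.01]
        h = make_hset(bx, sx, by, sy)
        ivw = mk.ivw_estimate(h, model="fixed")
        rob = mk.robust_ivw_estimate(h)
        assert abs(rob.theta - 0.5) < abs(ivw.theta - 0.5)

    def test_weight_scale_invariance(self, rng):
        h = random_hset(rng, 10)
        bx, sx, by, sy = h.arrays()
        scaled = make_hset(bx, sx, by, 3.7 * sy)
        a = mk.robust_ivw_estimate(h)
        b = mk.robust_ivw_estimate(scaled)
        assert b.theta == pytest.approx(a.theta, rel=1e-8)


class TestRaps:
    def test_vanishing_exposure_error_matches_ivw(self, three_iv_hset):
        bx, _sx, by, sy = three_iv_hset.arrays()
        h = make_hset(bx, [1e-8] * 3, by, sy)
        raps = mk.raps_estimate(h, loss="squared", overdispersion=False)
        ivw = mk.ivw_estimate(three_iv_hset, model="fixed")
        assert raps.theta == pytest.approx(ivw.theta, abs=1e-6)

    def test_exact_proportional_data(self):
        h = make_hset([0.1, 0.2, 0.3], [0.005] * 3, [0.07, 0.14, 0.21], [0.01] * 3)
        est = mk.raps_estimate(h)
        assert est.theta == pytest.approx(0.7, abs=1e-8)
        assert est.extras["tau2"] == pytest.approx(0.0, abs=1e-12)

    def test_huber_loss_bounds_outlier_influence(self, rng):
        h = random_hset(rng, 20, theta=0.4)
        bx, sx, by, sy = h.arrays()
        by_out = by.copy()
        by_out[0] += 30 * sy[0]
        h_out = make_hset(bx, sx, by_out, sy)
        raps = mk.raps_estimate(h_out, loss="huber")
        ivw = mk.ivw_estimate(h_out, model="fixed")
        assert abs(raps.theta - 0.4) < abs(ivw.theta - 0.4)


class TestOddsRatio:
    def test_null_effect(self):
        h = make_hset([0.1], [0.01], [0.0], [0.01], outcome_type="binary")
        est = mk.ivw_estimate(h, model="fixed")
        orr = mk.to_odds_ratio(est)
        assert orr.odds_ratio == pytest.approx(1.0)
        assert orr.ci_low > 0

    def test_reporting_shape(self):
        est = mk.MREstimate(method="ivw", theta=-0.0523, se=0.0598,
                            ci_low=-0.0523 - 1.959963984540054 * 0.0598,
                            ci_high=-0.0523 + 1.959963984540054 * 0.0598,
                            pval=0.38, n_iv=24, scale="log_odds")
        orr = mk.to_odds_ratio(est)
        assert round(orr.odds_ratio, 3) == 0.949
        assert round(orr.ci_low, 3) == 0.844
        assert round(orr.ci_high, 3) == 1.067

    def test_continuous_outcome_rejected(self, three_iv_hset):
        est = mk.ivw_estimate(three_iv_hset, model="fixed")
        with pytest.raises(UnitError):
            mk.to_odds_ratio(est)


class TestScaleEquivariance:
    @given(c=st.floats(min_value=0.2, max_value=5.0), seed=st.integers(0, 50))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_rescaling_exposure_rescales_estimates(self, c, seed):
        rng = np.random.default_rng(seed)
        h = random_hset(rng, 8)
        bx, sx, by, sy = h.arrays()
        h2 = make_hset(c * bx, c * sx, by, sy)
        for fn in (lambda s: mk.ivw_estimate(s, model="fixed"),
                   mk.egger_estimate,
                   lambda s: mk.weighted_median_estimate(s, n_boot=30, seed=9),
                   lambda s: mk.raps_estimate(s, loss="squared", overdispersion=False)):
            assert fn(h2).theta * c == pytest.approx(fn(h).theta, rel=1e-6, abs=1e-9)
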