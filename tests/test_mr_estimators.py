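import numpy as np
import pytest
import statsmodels.api as sm

from mrnetwork.mr_estimators import (
    EstimatorConfig,
    egger,
    fit_all_models,
    ivw,
    median_estimator,
    wald_ratios,
    weighted_mode,
)

from conftest import make_iset


def _random_iset(rng, n=50, slope=0.4, intercept=0.0, het=0.0):
    b_x = np.abs(rng.normal(0, 0.1, n)) + 0.02
    se_y = rng.uniform(0.005, 0.05, n)
    b_y = intercept + slope * b_x + rng.normal(0, se_y) + rng.normal(0, het, n)
    return make_iset(b_x, b_y, se_y)


class TestWaldRatios:
    def test_arithmetic(self):
        iset = make_iset([0.1], [0.05], [0.01])
        (r,) = wald_ratios(iset)
        assert r.theta == pytest.approx(0.5)
        assert r.se == pytest.approx(0.1)
        assert r.weight == pytest.approx(100.0)

    def test_zero_outcome_beta(self):
        iset = make_iset([0.1], [0.0], [0.01])
        (r,) = wald_ratios(iset)
        assert r.theta == 0.0

    def test_zero_exposure_beta_excluded_with_warning(self):
        iset = make_iset([0.1, 0.0], [0.05, 0.05], [0.01, 0.01])
        with pytest.warns(UserWarning, match="b_X = 0"):
            ratios = wald_ratios(iset)
        assert len(ratios) == 1

    def test_matches_brute_force(self, rng):
        iset = _random_iset(rng)
        ratios = wald_ratios(iset)
        for r, row in zip(ratios, iset.rows.itertuples(index=False)):
            assert r.theta == pytest.approx(row.b_Y / row.b_X)
            assert r.se == pytest.approx(row.se_Y / abs(row.b_X))


class TestIVW:
    def test_homogeneity_limit(self):
        # identical Wald ratios: Q = 0, RE se equals FE se (sigma truncated at 1)
        iset = make_iset([0.1, 0.2], [0.05, 0.10], [0.01, 0.01])
        fe = ivw(iset, "fixed")
        re = ivw(iset, "multiplicative_random")
        assert fe.beta == pytest.approx(0.5)
        assert re.beta == pytest.approx(0.5)
        assert re.se == pytest.approx(fe.se)

    def test_point_estimate_matches_wls_normal_equations(self):
        iset = make_iset([0.1, 0.2], [0.05, 0.30], [0.01, 0.01])
        got = ivw(iset, "fixed")
        x = np.array([0.1, 0.2])
        y = np.array([0.05, 0.30])
        w = np.array([1e4, 1e4])
        expected = np.sum(w * x * y) / np.sum(w * x * x)
        assert got.beta == pytest.approx(expected, abs=1e-12)

    def test_matches_statsmodels_wls_oracle(self, rng):
        iset = _random_iset(rng, het=0.02)
        x = iset.rows["b_X"].to_numpy()
        y = iset.rows["b_Y"].to_numpy()
        w = 1.0 / iset.rows["se_Y"].to_numpy() ** 2
        fit = sm.WLS(y, x[:, None], weights=w).fit()
        got = ivw(iset, "multiplicative_random")
        assert got.beta == pytest.approx(fit.params[0], abs=1e-10)
        # statsmodels scales by sqrt(RSS_w/(J-1)) without truncation; under
        # heterogeneity sigma > 1 so the scaled ses agree
        assert got.se == pytest.approx(fit.bse[0], rel=1e-8)

    def test_re_se_never_below_fe_se(self, rng):
        for _ in range(20):
            iset = _random_iset(rng, n=10, het=float(rng.uniform(0, 0.05)))
            fe = ivw(iset, "fixed")
            re = ivw(iset, "multiplicative_random")
            assert re.beta == pytest.approx(fe.beta)
            assert re.se >= fe.se - 1e-15

    def test_robust_resists_gross_outlier(self, rng):
        n = 30
        b_x = np.abs(rng.normal(0, 0.1, n)) + 0.05
        se_y = np.full(n, 0.01)
        b_y = 0.5 * b_x + rng.normal(0, se_y)
        b_y[0] += 2.0  # gross outlier
        iset = make_iset(b_x, b_y, se_y)
        plain = ivw(iset, "multiplicative_random")
        robust = ivw(iset, "robust")
        assert abs(robust.beta - 0.5) < abs(plain.beta - 0.5)
        assert abs(robust.beta - 0.5) < 0.05

    def test_requires_two_instruments(self):
        with pytest.raises(ValueError, match="at least 2"):
            ivw(make_iset([0.1], [0.05], [0.01]))


class TestEgger:
    def test_exact_fit_recovers_intercept_and_slope(self):
        b_x = np.array([0.1, 0.15, 0.2, 0.3, 0.4])
        b_y = 0.02 + 0.4 * b_x
        iset = make_iset(b_x, b_y, np.full(5, 0.01))
        res = egger(iset)
        assert res.beta == pytest.approx(0.4, abs=1e-12)
        assert res.egger_intercept == pytest.approx(0.02, abs=1e-12)

    def test_orientation_invariance(self):
        b_x = np.array([0.1, 0.15, 0.2, 0.3, 0.4])
        b_y = 0.02 + 0.4 * b_x + np.array([0.001, -0.002, 0.0, 0.002, -0.001])
        iset1 = make_iset(b_x, b_y, np.full(5, 0.01))
        b_x2, b_y2 = b_x.copy(), b_y.copy()
        b_x2[2] *= -1
        b_y2[2] *= -1
        iset2 = make_iset(b_x2, b_y2, np.full(5, 0.01))
        r1, r2 = egger(iset1), egger(iset2)
        assert r1.beta == pytest.approx(r2.beta, abs=1e-14)
        assert r1.egger_intercept == pytest.approx(r2.egger_intercept, abs=1e-14)

    def test_matches_statsmodels_wls_oracle(self, rng):
        iset = _random_iset(rng, intercept=0.01, het=0.02)
        x = iset.rows["b_X"].to_numpy()
        y = iset.rows["b_Y"].to_numpy()
        w = 1.0 / iset.rows["se_Y"].to_numpy() ** 2
        X = sm.add_constant(np.abs(x))
        fit = sm.WLS(y * np.sign(x), X, weights=w).fit()
        got = egger(iset)
        assert got.egger_intercept == pytest.approx(fit.params[0], abs=1e-10)
        assert got.beta == pytest.approx(fit.params[1], abs=1e-10)

    def test_requires_three_instruments(self):
        with pytest.raises(ValueError, match="at least 3"):
            egger(make_iset([0.1, 0.2], [0.04, 0.08], [0.01, 0.01]))


class TestMedian:
    def test_three_equal_weights_is_middle(self):
        iset = make_iset([1.0, 1.0, 1.0], [0.1, 0.5, 0.9], [0.1, 0.1, 0.1])
        ratios = wald_ratios(iset)
        res = median_estimator(ratios, iset, "simple")
        assert res.beta == pytest.approx(0.5)

    def test_degenerate_weight_limit(self):
        # nearly all weight on the third ratio: estimate approaches it
        iset = make_iset([1.0, 1.0, 1.0], [0.1, 0.5, 0.9], [10.0, 10.0, 0.001])
        ratios = wald_ratios(iset)
        res = median_estimator(ratios, iset, "inverse_variance")
        assert res.beta == pytest.approx(0.9, abs=1e-3)

    def test_hand_computed_interpolation(self):
        # thetas (0.1, 0.3, 0.6, 1.0), equal weights: p_k = (.125,.375,.625,.875)
        # interpolating 0.5 between 0.3 and 0.6 -> 0.45
        iset = make_iset([1.0] * 4, [0.1, 0.3, 0.6, 1.0], [0.1] * 4)
        ratios = wald_ratios(iset)
        res = median_estimator(ratios, iset, "simple")
        assert res.beta == pytest.approx(0.45)

    def test_weighted_hand_computed(self):
        # normalized weights (.1,.2,.3,.4): p_k = (.05,.20,.45,.80);
        # interpolating 0.5 between (0.45, 0.6) and (0.80, 1.0) gives
        # 0.6 + (0.05/0.35) * 0.4 = 0.6571428...
        se = 1.0 / np.sqrt(np.array([1.0, 2.0, 3.0, 4.0]))
        iset = make_iset([1.0] * 4, [0.1, 0.3, 0.6, 1.0], se)
        ratios = wald_ratios(iset)
        res = median_estimator(ratios, iset, "inverse_variance")
        assert res.beta == pytest.approx(0.6 + 0.4 * 0.05 / 0.35)

    def test_bootstrap_se_is_seeded(self):
        iset = make_iset([1.0] * 5, [0.1, 0.3, 0.5, 0.7, 0.9], [0.1] * 5)
        ratios = wald_ratios(iset)
        cfg = EstimatorConfig(seed=42)
        r1 = median_estimator(ratios, iset, "simple", cfg)
        r2 = median_estimator(ratios, iset, "simple", cfg)
        assert r1.se == r2.se


class TestMode:
    def test_degenerate_cluster(self):
        iset = make_iset([1.0] * 3, [0.5, 0.5, 0.5], [0.1] * 3)
        ratios = wald_ratios(iset)
        res = weighted_mode(ratios, iset)
        assert res.beta == pytest.approx(0.5, abs=1e-6)

    def test_majority_cluster_recovery(self, rng):
        theta = np.concatenate([0.3 + rng.normal(0, 0.01, 7), 1.5 + rng.normal(0, 0.01, 3)])
        iset = make_iset(np.ones(10), theta, np.full(10, 0.05))
        ratios = wald_ratios(iset)
        res = weighted_mode(ratios, iset, EstimatorConfig(seed=1))
        assert abs(res.beta - 0.3) < 0.1

    def test_bandwidth_scaling_preserves_two_cluster_order(self, rng):
        # cluster of 7 vs cluster of 3 far apart: doubling the bandwidth
        # multiplier never swaps which cluster holds the density maximum
        theta = np.concatenate([0.0 + rng.normal(0, 0.005, 7), 3.0 + rng.normal(0, 0.005, 3)])
        iset = make_iset(np.ones(10), theta, np.full(10, 0.05))
        ratios = wald_ratios(iset)
        r1 = weighted_mode(ratios, iset, EstimatorConfig(mode_phi=1.0, seed=2))
        r2 = weighted_mode(ratios, iset, EstimatorConfig(mode_phi=2.0, seed=2))
        assert abs(r1.beta) < 1.0 and abs(r2.beta) < 1.0  # both in majority cluster


class TestCrossEstimatorProperties:
    def test_sign_flip_equivariance_all_models(self, rng):
        iset1 = _random_iset(rng, n=12)
        rows2 = iset1.rows.copy()
        rows2.loc[3, ["b_X", "b_Y"]] *= -1.0
        iset2 = type(iset1)(exposure_id="X", outcome_id="Y", rows=rows2)
        cfg = EstimatorConfig(seed=5)
        for m1, m2 in zip(fit_all_models(iset1, cfg), fit_all_models(iset2, cfg)):
            assert m1.method == m2.method
            assert m1.beta == pytest.approx(m2.beta, abs=1e-10)

    def test_all_seven_agree_with_valid_strong_instruments(self, rng):
        # consistency suite: no pleiotropy, strong instruments -> all seven
        # within 2 combined standard errors of each other
        iset = _random_iset(rng, n=40, slope=0.35)
        results = fit_all_models(iset, EstimatorConfig(seed=9))
        assert len(results) == 7
        betas = {r.method: r for r in results}
        ref = betas["RE_IVW"]
        for r in results:
            tol = 2.0 * max(r.se, ref.se)
            assert abs(r.beta - ref.beta) <= tol, r.method

    def test_config_validation(self):
        with pytest.raises(ValueError):
            EstimatorConfig(bootstrap_B=10)
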