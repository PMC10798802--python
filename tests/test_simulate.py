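import numpy as np
import pytest
from scipy import stats

from cdenet.simulate import (
    CensoredSimConfig,
    UncensoredSimConfig,
    apply_censoring,
    baseline_hazard,
    calibrate_censoring_rate,
    conditional_hazard,
    draw_failure_times,
    gen_censored_records,
    gen_covariate_paths,
    gen_kernel_example,
    gen_uncensored,
    mean_function,
    triangular_cdf,
    triangular_ppf,
    true_cdf_kernel,
    true_cdf_uncensored,
)


class TestBaselineHazard:
    def test_zero_at_origin(self):
        assert baseline_hazard(0.0) == 0.0

    def test_midpoint_value(self):
        # 8 (1/2)^7 / (1 - (1/2)^8) = 0.0625 / 0.99609375
        assert baseline_hazard(50.0, tau=100.0) == pytest.approx(
            0.0625 / 0.99609375, rel=1e-12
        )

    def test_strictly_increasing(self):
        t = np.linspace(0.5, 99.0, 500)
        lam = baseline_hazard(t)
        assert np.all(np.diff(lam) > 0)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            baseline_hazard(100.0, tau=100.0)
        with pytest.raises(ValueError):
            baseline_hazard(-1.0)


class TestCovariatePaths:
    def test_fourier_path_at_zero(self):
        cov = gen_covariate_paths(5, seed=0)
        # sines vanish and cosines are 1 at t=0
        expected = cov.alpha[:, 0] + cov.alpha[:, 2] + cov.alpha[:, 4]
        np.testing.assert_allclose(cov.x1_at(np.array([0.0]))[:, 0], expected)

    def test_step_covariate_left_continuous(self):
        cov = gen_covariate_paths(3, seed=1)
        p = cov.path(0)
        q = cov.q[0]
        assert p.x2(q) == 0.0
        assert p.x2(q + 1e-9) == 1.0

    def test_static_covariate_laws(self):
        cov = gen_covariate_paths(10_000, seed=2)
        se = np.sqrt(0.6 * 0.4 / 10_000)
        assert abs(cov.x3.mean() - 0.6) < 3 * se
        assert set(np.unique(cov.x4)).issubset(set(range(6)))
        assert np.all((cov.x5 > 0) & (cov.x5 < 1))

    def test_path_object_matches_vectorized_values(self):
        cov = gen_covariate_paths(4, seed=3)
        t = np.array([0.0, 10.0, 55.5, 99.0])
        p = cov.path(2)
        np.testing.assert_allclose(p(t)[:, 0], cov.x1_at(t, idx=np.array([2]))[0])
        np.testing.assert_allclose(p(t)[:, 1], cov.x2_at(t, idx=np.array([2]))[0])


class TestConditionalHazard:
    def test_reduces_to_baseline_with_zero_covariates(self):
        t = 30.0
        for setup in ("ph", "nonph"):
            assert conditional_hazard(t, 0, 0, 0, 0, 0, setup) == pytest.approx(
                baseline_hazard(t)
            )

    def test_proportional_hazards_ratio(self):
        a = conditional_hazard(40.0, 0.3, 1, 1, 2, 0.5, "ph")
        b = conditional_hazard(40.0, 0.3, 1, 0, 2, 0.5, "ph")
        assert a / b == pytest.approx(np.exp(2))

    def test_log_ratio_constant_over_time_in_ph_setup(self):
        ts = np.array([10.0, 35.0, 70.0, 95.0])
        r = conditional_hazard(ts, 0.2, 0, 1, 3, 0.1, "ph") / conditional_hazard(
            ts, 0.8, 1, 0, 1, 0.9, "ph"
        )
        assert np.allclose(r, r[0])

    def test_nonph_even_in_x1(self):
        assert conditional_hazard(20.0, 1.0, 0, 0, 0, 0, "nonph") == pytest.approx(
            conditional_hazard(20.0, -1.0, 0, 0, 0, 0, "nonph")
        )

    def test_unknown_setup(self):
        with pytest.raises(ValueError):
            conditional_hazard(1.0, 0, 0, 0, 0, 0, "weird")


class TestFailureTimes:
    def test_constant_hazard_matches_exponential(self):
        lam = 0.08
        cov = gen_covariate_paths(5000, seed=4)
        T = draw_failure_times(
            cov, "ph", seed=5, hazard_override=lambda t: np.full_like(t, lam)
        )
        inner = T[T < 100.0]  # administrative cap excluded
        # KS against the censored-at-tau exponential: compare on uncapped draws
        res = stats.kstest(inner, lambda x: stats.expon.cdf(x, scale=1 / lam) /
                           stats.expon.cdf(100.0, scale=1 / lam))
        assert res.pvalue > 0.01

    def test_reproducible(self):
        cov = gen_covariate_paths(50, seed=6)
        T1 = draw_failure_times(cov, "ph", seed=7)
        T2 = draw_failure_times(cov, "ph", seed=7)
        np.testing.assert_array_equal(T1, T2)

    def test_riemann_grid_refinement_stability(self):
        # halving the step changes failure-time quantiles by well under 0.5%
        cov = gen_covariate_paths(5000, seed=8)
        T1 = draw_failure_times(cov, "ph", delta_s=0.01, seed=9)
        T2 = draw_failure_times(cov, "ph", delta_s=0.005, seed=9)
        q1 = np.quantile(T1, [0.25, 0.5, 0.75])
        q2 = np.quantile(T2, [0.25, 0.5, 0.75])
        assert np.all(np.abs(q1 - q2) / q2 < 0.005)


class TestCensoring:
    def test_rate_extremes(self):
        T = np.random.default_rng(0).exponential(10, 2000)
        _, d_lo = apply_censoring(T, 1e-9, tau=1e9, seed=1)
        _, d_hi = apply_censoring(T, 1e6, tau=1e9, seed=1)
        assert (1 - d_lo).mean() < 0.01
        assert (1 - d_hi).mean() > 0.99

    def test_observed_time_is_minimum(self):
        T = np.random.default_rng(3).exponential(5, 200)
        y, d = apply_censoring(T, 0.5, seed=2)
        assert np.all(y <= T)
        # an event means the failure time itself was observed
        np.testing.assert_array_equal(y[d == 1], T[d == 1])
        # a censored subject was observed strictly before failing (or capped)
        assert np.all((y[d == 0] < T[d == 0]) | (y[d == 0] == 100.0))

    def test_calibrated_rate_hits_target(self):
        rate = calibrate_censoring_rate("ph", 0.20, seed=10, m=20000)
        # verify on an independent draw
        cov = gen_covariate_paths(10_000, seed=11)
        T = draw_failure_times(cov, "ph", seed=12)
        _, delta = apply_censoring(T, rate, seed=13)
        assert (1 - delta).mean() == pytest.approx(0.20, abs=0.015)

    def test_invalid_target(self):
        with pytest.raises(ValueError):
            calibrate_censoring_rate("ph", 1.5, seed=0, m=100)


class TestUncensoredGenerator:
    def test_error_is_mean_zero_setup1(self):
        _, _, info = gen_uncensored(UncensoredSimConfig(40_000, 1, 0.5, seed=14))
        eps = info["eps"]
        assert abs(eps.mean()) < 3 * eps.std() / np.sqrt(len(eps))

    def test_zero_noise_scale_degenerates_to_mean_function(self):
        X, y, info = gen_uncensored(UncensoredSimConfig(500, 2, 0.5, seed=15))
        mask = info["g"] == 0  # x1 = 0 never happens; check tiny g instead
        m = mean_function(X)
        small = info["g"] < 1e-4
        assert np.allclose(y[small], m[small], atol=1e-3)

    def test_covariate_truncations(self):
        X, _, _ = gen_uncensored(UncensoredSimConfig(20_000, 1, 0.5, seed=16))
        assert np.all(np.abs(X[:, 0]) <= 3)
        assert set(np.unique(X[:, 4])).issubset(set(range(6)))

    def test_setup2_error_covariate_correlation(self):
        X, _, info = gen_uncensored(UncensoredSimConfig(30_000, 2, 0.5, seed=17))
        r = np.corrcoef(X[:, 0], info["x6"])[0, 1]
        assert r == pytest.approx(0.5, abs=0.03)

    def test_reproducible(self):
        a = gen_uncensored(UncensoredSimConfig(100, 1, 0.5, seed=18))
        b = gen_uncensored(UncensoredSimConfig(100, 1, 0.5, seed=18))
        np.testing.assert_array_equal(a[1], b[1])

    def test_true_cdf_is_probability_integral_transform(self):
        cfg = UncensoredSimConfig(800, 1, 0.5, seed=19)
        X, y, _ = gen_uncensored(cfg)
        pit = np.array(
            [true_cdf_uncensored(x, yy, 1, 0.5, n_mc=20_000)[0] for x, yy in zip(X, y)]
        )
        assert abs(pit.mean() - 0.5) < 3 * pit.std() / np.sqrt(len(pit))
        assert np.all((pit >= 0) & (pit <= 1))


class TestKernelDesign:
    def test_triangular_cdf_symmetry_and_support(self):
        assert triangular_cdf(0.0) == 0.5
        assert triangular_cdf(-1.0) == 0.0 and triangular_cdf(-5.0) == 0.0
        assert triangular_cdf(1.0) == 1.0 and triangular_cdf(5.0) == 1.0

    def test_ppf_inverts_cdf(self):
        u = np.linspace(0.01, 0.99, 50)
        np.testing.assert_allclose(triangular_cdf(triangular_ppf(u)), u, atol=1e-12)

    def test_true_cdf_half_at_mean(self):
        for dims in (1, 2):
            x = np.array([0.3, -0.4])[:dims]
            m = 2 * np.sin(3.1416 * x[0]) + (x[1] if dims == 2 else 0.0)
            assert true_cdf_kernel(x, m, dims) == pytest.approx(0.5)

    def test_noise_moments(self):
        X, y = gen_kernel_example(100_000, 1, seed=20)
        eps = y - 2 * np.sin(3.1416 * X[:, 0])
        assert abs(eps.mean()) < 3 * eps.std() / np.sqrt(len(eps))
        assert np.all(np.abs(eps) <= 1.0)
        assert np.all(np.abs(X) <= 1.0)

    def test_dims_validation(self):
        with pytest.raises(ValueError):
            gen_kernel_example(10, 3, seed=0)


def test_gen_censored_records_end_to_end():
    cfg = CensoredSimConfig(30, "nonph", 0.5, seed=21)
    records, info = gen_censored_records(cfg, rate=0.05)
    assert len(records) == 30
    assert all(0 <= r.y <= 100.0 for r in records)
    assert all(r.delta in (0, 1) for r in records)
    # same config, same records
    records2, _ = gen_censored_records(cfg, rate=0.05)
    np.testing.assert_array_equal([r.y for r in records], [r.y for r in records2])
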