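"""Downsampling curves, SD/performance fits, N_c and Yec."""

import numpy as np
import pytest

import samplecast as sc
from samplecast.extrapolation import (
    PerformanceCurve,
    downsample_sizes,
    extrapolate_from_curve,
    stratified_subsample,
    _chain_indices,
)


def make_curve(sizes, means, sds, metric="youden", step=None):
    sizes = np.asarray(sizes)
    return PerformanceCurve(metric, "test", step or int(sizes[0] - sizes[1]),
                            sizes, means, sds, n_runs=50)


def ols_normal_equations(x, y):
    """Closed-form least squares via the normal equations."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    a = np.c_[np.ones_like(x), x]
    beta = np.linalg.solve(a.T @ a, a.T @ y)
    return beta[0], beta[1]


class TestSizes:
    def test_nine_point_use_case_grid(self):
        np.testing.assert_array_equal(
            downsample_sizes(84, 8, 20),
            [84, 76, 68, 60, 52, 44, 36, 28, 20])

    def test_three_points_is_the_minimum(self):
        np.testing.assert_array_equal(downsample_sizes(36, 8, 20), [36, 28, 20])
        with pytest.raises(ValueError, match="insufficient patients"):
            downsample_sizes(20, 8, 20)

    def test_subsample_counts_follow_pool_ratio(self):
        labels = np.r_[np.ones(30, int), np.zeros(90, int)]
        rng = np.random.default_rng(0)
        idx = stratified_subsample(labels, 40, rng)
        assert labels[idx].sum() == 10 and len(idx) == 40

    def test_subsample_keeps_both_classes_at_tiny_sizes(self):
        labels = np.r_[np.ones(2, int), np.zeros(98, int)]
        rng = np.random.default_rng(1)
        idx = stratified_subsample(labels, 5, rng)
        assert 1 <= labels[idx].sum() <= 4

    def test_nested_chains_are_nested_and_stratified(self):
        labels = np.r_[np.ones(60, int), np.zeros(140, int)]
        rng = np.random.default_rng(2)
        sizes = np.array([100, 80, 60, 40])
        chain = _chain_indices(labels, sizes, rng, nested=True)
        for bigger, smaller in zip(chain, chain[1:]):
            assert set(smaller) <= set(bigger)
        for s, idx in zip(sizes, chain):
            assert len(idx) == s
            assert labels[idx].sum() == round(s * 0.3)


class TestSdFits:
    def test_exact_line_recovered_with_exact_crossing(self):
        sizes = np.array([100, 80, 60, 40, 20])
        curve = make_curve(sizes, np.zeros(5), 0.1 - 0.001 * sizes)
        fit = sc.fit_sd_linear(curve)
        assert fit.a == pytest.approx(0.1, abs=1e-12)
        assert fit.b == pytest.approx(0.001, abs=1e-12)
        assert fit.n_c == pytest.approx(100.0)

    def test_constant_sd_flagged_no_crossing_and_capped(self):
        curve = make_curve([60, 50, 40], [0, 0, 0], [0.05, 0.05, 0.05])
        fit = sc.fit_sd_linear(curve)
        assert "no_zero_crossing" in fit.flags
        assert fit.n_c == 10 * 60

    def test_noisy_line_matches_normal_equations_oracle(self):
        sizes = np.arange(20, 120, 10)
        for seed in range(20):
            rng = np.random.default_rng(seed)
            sds = np.clip(0.3 - 0.002 * sizes + rng.normal(0, 0.01, len(sizes)),
                          0, None)
            curve = make_curve(sizes[::-1], np.zeros(len(sizes)), sds[::-1])
            fit = sc.fit_sd_linear(curve)
            a, slope = ols_normal_equations(sizes[::-1], sds[::-1])
            assert fit.a == pytest.approx(a, abs=1e-10)
            assert fit.b == pytest.approx(-slope, abs=1e-10)

    def test_log_model_analytic_root(self):
        sizes = np.array([90, 70, 50, 30])
        curve = PerformanceCurve("youden", "t", 20, sizes, np.zeros(4),
                                 0.5 - 0.1 * np.log(sizes), 50)
        fit = sc.fit_sd_log(curve)
        assert fit.n_c == pytest.approx(np.exp(5.0), rel=1e-9)

    def test_log_base_change_leaves_nc_invariant(self):
        """Fitting against log10 sizes rescales a' and b' but not N_c."""
        sizes = np.array([90, 70, 50, 30])
        rng = np.random.default_rng(3)
        sds = np.clip(0.4 - 0.07 * np.log(sizes) + rng.normal(0, 0.005, 4), 0, None)
        curve = PerformanceCurve("youden", "t", 20, sizes, np.zeros(4), sds, 50)
        fit = sc.fit_sd_log(curve)
        a10, s10 = ols_normal_equations(np.log10(sizes), sds)
        n_c_base10 = 10 ** (a10 / -s10)
        assert fit.n_c == pytest.approx(n_c_base10, rel=1e-9)

    def test_negative_decay_capped(self):
        curve = PerformanceCurve("youden", "t", 20, np.array([90, 70, 50]),
                                 np.zeros(3), np.array([0.1, 0.08, 0.06]), 50)
        fit = sc.fit_sd_log(curve)   # SD grows with size -> b' < 0
        assert "no_zero_crossing" in fit.flags and fit.n_c == 900


class TestPerfFit:
    def test_exact_log_curve_recovered(self):
        sizes = np.array([100, 80, 60, 40])
        means = 0.2 + 0.1 * np.log(sizes)
        curve = make_curve(sizes, means, np.full(4, 0.07))
        fit = sc.fit_perf_weighted_log(curve, "positive")
        assert fit.c == pytest.approx(0.2, abs=1e-10)
        assert fit.d == pytest.approx(0.1, abs=1e-10)
        assert fit.flags == ()

    def test_equal_sds_reduce_to_unweighted_ols(self):
        rng = np.random.default_rng(4)
        sizes = np.array([100, 80, 60, 40, 20])
        means = 0.3 + 0.05 * np.log(sizes) + rng.normal(0, 0.02, 5)
        curve = make_curve(sizes, means, np.full(5, 0.123))
        fit = sc.fit_perf_weighted_log(curve, "positive")
        c, d = ols_normal_equations(np.log(sizes), means)
        assert fit.c == pytest.approx(c, abs=1e-10)
        assert fit.d == pytest.approx(d, abs=1e-10)

    def test_zero_sd_point_floored_not_infinite(self):
        sizes = np.array([60, 50, 40])
        curve = make_curve(sizes, [0.5, 0.45, 0.4], [0.0, 0.05, 0.08], step=10)
        fit = sc.fit_perf_weighted_log(curve, "positive")
        assert np.isfinite(fit.c) and np.isfinite(fit.d)

    def test_wrong_sign_flagged_but_fit_returned(self):
        sizes = np.array([100, 80, 60])
        means = 0.9 - 0.1 * np.log(sizes)     # decaying
        curve = make_curve(sizes, means, np.full(3, 0.05), step=20)
        fit = sc.fit_perf_weighted_log(curve, "positive")
        assert "wrong_sign_slope" in fit.flags
        assert fit.d == pytest.approx(-0.1, abs=1e-10)


class TestYec:
    def test_direct_evaluation(self):
        fit = sc.fit_perf_weighted_log(
            make_curve(np.array([100, 80, 60]),
                       0.2 + 0.1 * np.log([100, 80, 60]),
                       np.full(3, 0.05), step=20), "positive")
        yec, flags = sc.extrapolate_yec(fit, 100, "youden")
        assert yec == pytest.approx(0.2 + 0.1 * np.log(100))
        assert flags == ()

    def test_clamped_to_metric_range(self):
        from samplecast.extrapolation import PerfFit
        yec, flags = sc.extrapolate_yec(PerfFit(0.9, 0.2), 10.0, "youden")
        assert yec == 1.0 and "clamped" in flags
        yec, _ = sc.extrapolate_yec(PerfFit(-0.5, 0.0), 10.0, "auc")
        assert yec == 0.0


class TestStability:
    def test_documented_example(self):
        sizes = [40, 48, 56, 64, 72]
        means = [0.40, 0.45, 0.505, 0.507, 0.509]
        assert sc.stability_reached(sizes, means, 8) == 56

    def test_alternating_sequence_never_stable(self):
        sizes = list(range(10, 60, 10))
        means = [0.5, 0.55, 0.5, 0.55, 0.5]
        assert sc.stability_reached(sizes, means, 10, tol=0.01) is None

    def test_non_constant_step_rejected(self):
        with pytest.raises(ValueError, match="constant step"):
            sc.stability_reached([10, 20, 35], [0.1, 0.1, 0.1], 10)

    def test_matches_brute_force_suffix_scan(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            n = int(rng.integers(2, 12))
            sizes = np.arange(n) * 8 + 16
            means = rng.normal(0.5, 0.03, n)
            got = sc.stability_reached(sizes, means, 8, tol=0.02)
            expected = None
            for start in range(n - 1):
                diffs = np.abs(np.diff(means[start:]))
                if (diffs <= 0.02).all():
                    expected = int(sizes[start])
                    break
            assert got == expected


class TestParameterRecovery:
    def test_noisy_generative_model_recovered_with_small_bias(self):
        """Data generated from the SD-decay and log-performance models with
        sigma = 0.01 noise: mean coefficient error < 0.005."""
        sizes = np.arange(160, 30, -10)
        a, b, c, d = 0.30, 0.0015, 0.10, 0.08
        err_a, err_b, err_c, err_d = [], [], [], []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            sds = a - b * sizes + rng.normal(0, 0.01, len(sizes))
            means = c + d * np.log(sizes) + rng.normal(0, 0.01, len(sizes))
            curve = PerformanceCurve("youden", "t", 10, sizes, means,
                                     np.clip(sds, 1e-4, None), 50)
            sd_fit = sc.fit_sd_linear(curve)
            perf_fit = sc.fit_perf_weighted_log(curve, "positive")
            err_a.append(sd_fit.a - a)
            err_b.append(sd_fit.b - b)
            err_c.append(perf_fit.c - c)
            err_d.append(perf_fit.d - d)
        for errs in (err_a, err_b, err_c, err_d):
            assert abs(np.mean(errs)) < 0.005


class TestCurvesOnData:
    def test_univariate_curve_decays_with_size(self):
        """Resubstitution optimism: the mean YI curve decreases with
        subsample size for an informative feature."""
        from scipy.stats import spearmanr
        spec = sc.SimulationSpec(150, 250, 1, [0.8], seed=10)
        cohort = sc.simulate_cohort(spec)
        curve = sc.build_downsampling_curve(
            cohort, "roc:f00", "youden", step=50, n_runs=40, base_seed=0,
            min_size=50, top_size=350)
        rho = spearmanr(curve.sizes, curve.means).statistic
        assert rho < 0

    def test_univariate_report_has_negative_slope_and_distant_nc(self):
        spec = sc.SimulationSpec(150, 250, 1, [0.8], seed=10)
        cohort = sc.simulate_cohort(spec)
        rep = sc.predict_performance(cohort, "roc:f00", "youden", step=30,
                                     n_runs=30, base_seed=1, min_size=40,
                                     top_size=200)
        assert rep.perf_fit.d < 0
        assert rep.n_c > 200
        assert -1 <= rep.yec <= 1

    def test_ml_curve_values_within_metric_ranges(self, wdbc):
        spec = sc.classifier_spec("C9")
        yi_curve, auc_curve = sc.build_ml_curve_pair(
            wdbc, spec, step=20, n_runs=4, base_seed=0, min_size=40,
            top_size=100)
        assert ((yi_curve.means >= -1) & (yi_curve.means <= 1)).all()
        assert ((auc_curve.means >= 0) & (auc_curve.means <= 1)).all()
        rep = extrapolate_from_curve(auc_curve, "ml")
        assert 0 <= rep.yec <= 1
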