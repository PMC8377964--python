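"""Cohort statistics: gated tests, calibrations, correlations, filters."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats as sps

from hyalkit.stats import (
    FiveParamLogistic,
    constrained_quad_fit,
    ddct_fold_change,
    fit_5pl,
    floor_undetectable,
    intra_assay_cv,
    invert_5pl,
    normality_gated_test,
    run_cohort_analysis,
    serial_dilution_factor,
    spearman,
    viscometer_replicate_filter,
)


class TestGatedTest:
    def test_identical_groups_null(self):
        v = np.concatenate([np.arange(10.0) + 1, np.arange(10.0) + 1])
        g = np.array(["a"] * 10 + ["b"] * 10)
        rep = normality_gated_test(v, g)
        assert rep.p_value > 0.9
        assert rep.effect == pytest.approx(0.0)

    def test_shifted_normals_take_t_branch(self):
        rng = np.random.default_rng(1)
        v = np.concatenate([rng.normal(0, 1, 50), rng.normal(1, 1, 50)])
        g = np.array(["a"] * 50 + ["b"] * 50)
        rep = normality_gated_test(v, g, skew_policy="none")
        assert rep.branch == "t-test"
        assert rep.p_value < 0.01
        assert "mean" in rep.group_summaries["a"]

    def test_heavy_tail_engages_cbrt(self):
        rng = np.random.default_rng(2)
        v = np.concatenate([rng.lognormal(0, 1.5, 40), rng.lognormal(0.5, 1.5, 40)])
        g = np.array(["a"] * 40 + ["b"] * 40)
        rep = normality_gated_test(v, g)
        assert rep.transform == "cbrt"

    def test_left_skew_engages_log(self):
        rng = np.random.default_rng(3)
        # left-skewed positive data: reflected lognormal
        base = 100 - rng.lognormal(1.5, 0.8, 80)
        base = base[base > 0]
        g = np.array(["a", "b"] * (len(base) // 2) + ["a"] * (len(base) % 2))
        rep = normality_gated_test(base, g)
        assert rep.transform == "log"

    def test_wilcoxon_p_transform_invariant(self):
        """Rank-sum p-values are unchanged by monotone transforms."""
        rng = np.random.default_rng(4)
        v = rng.lognormal(0, 1, 60)
        g = np.array(["a", "b"] * 30)
        p_cbrt = normality_gated_test(v, g, skew_policy="cbrt")
        p_log = normality_gated_test(v, g, skew_policy="log")
        if p_cbrt.branch == "wilcoxon" and p_log.branch == "wilcoxon":
            assert p_cbrt.p_value == pytest.approx(p_log.p_value, rel=1e-9)

    def test_type_one_error_calibrated(self):
        """Null rejection rate at alpha=0.05 in [0.03, 0.07] over 1000 sims."""
        rng = np.random.default_rng(42)
        hits = 0
        for _ in range(1000):
            v = rng.lognormal(0, 1, size=40)
            g = np.array(["a"] * 20 + ["b"] * 20)
            hits += normality_gated_test(v, g).p_value < 0.05
        assert 0.03 <= hits / 1000 <= 0.07

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            normality_gated_test([1, 2, 3, 4], ["a", "a", "b", "b"])


class TestFloorAndDdct:
    def test_floor_examples(self):
        np.testing.assert_allclose(floor_undetectable([0, 0, 5.2]), [1, 1, 5.2])
        np.testing.assert_allclose(floor_undetectable([3.0, 4.0]), [3.0, 4.0])
        with pytest.raises(ValueError):
            floor_undetectable([-1.0])

    def test_fold_change_closed_forms(self):
        # healthy median dCT = 5; ddCT -1 -> fold 2, ddCT 2 -> fold 0.25
        ct_gene = [10.0, 9.0, 12.0]
        ct_ref = [5.0, 5.0, 5.0]
        groups = ["healthy", "healthy", "healthy"]
        fc = ddct_fold_change(ct_gene, ct_ref, groups)
        np.testing.assert_allclose(fc, [1.0, 2.0, 0.25])

    def test_healthy_median_fold_is_one(self):
        rng = np.random.default_rng(0)
        n = 31
        ct_ref = rng.normal(15, 0.5, n)
        ct_gene = ct_ref + rng.normal(8, 1, n)
        fc = ddct_fold_change(ct_gene, ct_ref, ["healthy"] * n)
        assert np.median(fc) == pytest.approx(1.0, rel=1e-12)

    def test_mean_centering_option(self):
        fc = ddct_fold_change([10, 12], [5, 5], ["healthy", "healthy"], center="mean")
        assert np.prod(fc) == pytest.approx(1.0)  # geometric mean 1 under mean centering


class TestFivePL:
    TRUTH = FiveParamLogistic(12.0, 980.0, 0.8, 1.7, 0.8)

    def test_noiseless_parameter_recovery(self):
        x = np.geomspace(0.02, 50, 12)
        fit = fit_5pl(x, self.TRUTH(x))
        for name in "abcdf":
            assert getattr(fit, name) == pytest.approx(
                getattr(self.TRUTH, name), rel=1e-4
            )

    def test_midpoint_value_with_f_one(self):
        p = FiveParamLogistic(10.0, 100.0, 2.0, 1.5, 1.0)
        assert p(2.0) == pytest.approx(10.0 + 100.0 / 2)

    def test_flat_responses_rejected(self):
        with pytest.raises(ValueError):
            fit_5pl(np.geomspace(0.1, 10, 6), np.full(6, 5.0))

    def test_round_trip_inversion(self):
        x = np.geomspace(0.01, 100, 50)
        y = self.TRUTH(x)
        inv = np.array([invert_5pl(float(v), self.TRUTH).conc for v in y])
        assert np.max(np.abs(inv - x) / x) < 1e-8

    def test_asymptote_censored(self):
        res = invert_5pl(self.TRUTH.a, self.TRUTH)
        assert res.censored is not None
        assert np.isnan(res.conc)

    def test_f_one_matches_4pl_oracle(self):
        """With f = 1 the model is the standard 4PL; an independent 4PL fit
        on the same data gives the same curve."""
        p = FiveParamLogistic(20.0, 400.0, 1.5, 2.0, 1.0)
        x = np.geomspace(0.05, 40, 10)
        y = p(x)

        def fourpl(x, a, b, c, d):
            return a + b / (1.0 + (x / c) ** d)

        popt, _ = optimize.curve_fit(fourpl, x, y, p0=[15, 300, 1, 1], maxfev=10000)
        fit = fit_5pl(x, y)
        np.testing.assert_allclose(fit(x), fourpl(x, *popt), rtol=1e-6)


class TestConstrainedQuad:
    def test_study_curve_recovered_exactly(self):
        x = np.linspace(0.05, 1.5, 17)
        fit = constrained_quad_fit(x, 1 + 434 * x**2)
        assert fit.B2 == pytest.approx(434.0, rel=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_flat_unit_data_gives_zero(self):
        assert constrained_quad_fit([0.1, 0.5, 1.0], [1, 1, 1]).B2 == 0.0

    def test_matches_generic_constrained_solver(self):
        """Closed form equals lstsq of (y-1) on x^2 to 1e-10."""
        rng = np.random.default_rng(9)
        x = rng.uniform(0.05, 2, 40)
        y = 1 + 300 * x**2 + rng.normal(0, 5, 40)
        fit = constrained_quad_fit(x, y)
        oracle = np.linalg.lstsq((x**2)[:, None], y - 1, rcond=None)[0][0]
        assert abs(fit.B2 - oracle) < 1e-10

    def test_all_zero_x_rejected(self):
        with pytest.raises(ValueError):
            constrained_quad_fit([0.0, 0.0], [1.0, 2.0])


class TestCorrelationCvFilter:
    def test_spearman_monotone_extremes(self):
        x = np.array([1.0, 2, 4, 8, 20])
        assert spearman(x, x**3).rho == pytest.approx(1.0)
        assert spearman(x, -x).rho == pytest.approx(-1.0)

    def test_spearman_independent_normals(self):
        rng = np.random.default_rng(17)
        res = spearman(rng.normal(size=100), rng.normal(size=100))
        assert abs(res.rho) < 0.2
        assert res.p_value > 0.05

    def test_spearman_constant_undefined(self):
        res = spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert res.undefined

    def test_intra_assay_cv_hand_value(self):
        df = pd.DataFrame({"sample_id": ["a", "a"], "value": [9.0, 11.0]})
        assert intra_assay_cv(df) == pytest.approx(100 * np.sqrt(2) / 10, rel=1e-9)

    def test_intra_assay_cv_identical_replicates(self):
        df = pd.DataFrame({"sample_id": ["a", "a", "b", "b"], "value": [5, 5, 7, 7]})
        assert intra_assay_cv(df) == 0.0

    def test_cv_recovery_from_synthetic_plate(self):
        """Plate simulated at 6.5% replicate CV is recovered within
        sampling error."""
        rng = np.random.default_rng(3)
        rows = []
        for i in range(60):
            mu = rng.uniform(0.1, 1.5)
            for v in rng.normal(mu, 0.065 * mu, size=2):
                rows.append({"sample_id": f"s{i}", "value": v})
        cv = intra_assay_cv(pd.DataFrame(rows))
        assert cv == pytest.approx(6.5, abs=1.5)

    def test_serial_dilution_factor(self):
        assert serial_dilution_factor([20, 100]) == 2000.0
        with pytest.raises(ValueError):
            serial_dilution_factor([])

    def test_viscometer_filter_retains_five_of_seven(self):
        segs = [(50, 2.0), (50, 2.1), (75, 1.9), (75, 2.0), (100, 1.95), (100, 2.0), (125, 1.9)]
        res = viscometer_replicate_filter(segs)
        assert len(res.retained) == 5
        assert res.excluded_flow_rate == 50
        assert not res.empty

    def test_viscometer_filter_single_rate_flagged(self):
        res = viscometer_replicate_filter([(50, 2.0), (50, 2.1)])
        assert res.retained == [] and res.empty

    def test_viscometer_filter_two_rates(self):
        res = viscometer_replicate_filter([(50, 2.0), (75, 1.9)])
        assert res.retained == [(75, 1.9)]


class TestCohortDriver:
    def test_single_group_summaries_only(self):
        df = pd.DataFrame({"group": ["a"] * 5, "x": [1.0, 2, 3, 4, 5]})
        rep = run_cohort_analysis(df)
        assert rep["variables"]["x"]["summary_only"]

    def test_sparse_variable_skipped_with_warning(self):
        df = pd.DataFrame(
            {"group": ["a"] * 5 + ["b"] * 5, "x": [1.0, 2, np.nan, np.nan, np.nan] + [4.0] * 5}
        )
        rep = run_cohort_analysis(df)
        assert any("x" in w for w in rep["warnings"])
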