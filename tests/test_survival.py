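"""Cox fitter vs independent oracles, meta-analysis, KM/log-rank, curves."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from reactivepdl1 import (ConvergenceError, DegenerateInputError,
                          EstimationError, ValidationError, adjusted_curves,
                          fit_cox, generate_cohort, hr_concordance, km_curve,
                          logrank, meta_fixed_effects, per_cohort_hr)
from reactivepdl1.errors import AlignmentError
from reactivepdl1.survival import CoxFit
from _oracles import oracle_partial_loglik


class TestFitCoxOracle:
    def test_matches_partial_likelihood_maximizer(self, survival_frame):
        clinical, covariate = survival_frame
        t = clinical["time"].to_numpy()
        d = clinical["event"].to_numpy()
        x = covariate.to_numpy()
        opt = minimize_scalar(
            lambda b: -oracle_partial_loglik(b, t, d, x),
            bounds=(-10, 10), method="bounded",
            options={"xatol": 1e-10})
        fit = fit_cox(clinical, covariate)
        assert abs(fit.coefficients[0] - opt.x) < 1e-4

    @pytest.mark.parametrize("ties", ["efron", "breslow"])
    def test_tied_event_times_both_methods(self, ties):
        clinical = pd.DataFrame({
            "sample_id": [f"P{i}" for i in range(8)],
            "time": [1.0, 1.0, 2.0, 2.0, 3.0, 3.0, 4.0, 5.0],
            "event": [1, 1, 1, 0, 1, 1, 0, 1],
            "cohort": "c",
        })
        covariate = pd.Series([0.5, -1.0, 0.0, 2.0, 1.5, -0.5, 1.0, -2.0],
                              index=clinical["sample_id"], name="x")
        t = clinical["time"].to_numpy()
        d = clinical["event"].to_numpy()
        x = covariate.to_numpy()
        opt = minimize_scalar(
            lambda b: -oracle_partial_loglik(b, t, d, x, ties=ties),
            bounds=(-10, 10), method="bounded", options={"xatol": 1e-10})
        fit = fit_cox(clinical, covariate, ties=ties)
        assert fit.ties_method == ties
        assert abs(fit.coefficients[0] - opt.x) < 1e-4

    def test_efron_breslow_identical_without_ties(self, survival_frame):
        clinical, covariate = survival_frame
        fe = fit_cox(clinical, covariate, ties="efron")
        fb = fit_cox(clinical, covariate, ties="breslow")
        np.testing.assert_allclose(fe.coefficients, fb.coefficients,
                                   atol=1e-8)

    def test_agrees_with_lifelines(self, small_cohort):
        from lifelines import CoxPHFitter
        c = small_cohort
        ids = c.sample_ids
        cov = pd.DataFrame({
            "CD8A": c.expression.loc["CD8A", ids].to_numpy(),
            "CD274": c.expression.loc["CD274", ids].to_numpy()}, index=ids)
        fit = fit_cox(c.clinical, cov)
        df = c.clinical[["time", "event"]].copy()
        df[["CD8A", "CD274"]] = cov.to_numpy()
        cph = CoxPHFitter().fit(df, "time", "event")
        np.testing.assert_allclose(fit.coefficients,
                                   cph.params_.to_numpy(), rtol=1e-4)
        np.testing.assert_allclose(fit.standard_errors,
                                   cph.standard_errors_.to_numpy(), rtol=1e-4)


class TestFitCoxContracts:
    def test_negation_flips_sign_exactly(self, survival_frame):
        clinical, covariate = survival_frame
        f1 = fit_cox(clinical, covariate)
        f2 = fit_cox(clinical, -covariate)
        assert np.isclose(f1.coefficients[0], -f2.coefficients[0], atol=1e-8)
        assert np.isclose(f1.standard_errors[0], f2.standard_errors[0],
                          atol=1e-8)

    def test_scaling_equivariance(self, survival_frame):
        clinical, covariate = survival_frame
        f1 = fit_cox(clinical, covariate)
        f2 = fit_cox(clinical, 4.0 * covariate)
        assert np.isclose(f2.coefficients[0], f1.coefficients[0] / 4.0,
                          rtol=1e-6)
        assert np.isclose(f2.standard_errors[0], f1.standard_errors[0] / 4.0,
                          rtol=1e-6)

    def test_centering_leaves_hr_invariant(self, survival_frame):
        clinical, covariate = survival_frame
        f1 = fit_cox(clinical, covariate)
        f2 = fit_cox(clinical, covariate - covariate.mean())
        assert np.isclose(f1.hazard_ratios[0], f2.hazard_ratios[0], rtol=1e-8)

    def test_zero_events_is_estimation_error(self, survival_frame):
        clinical, covariate = survival_frame
        clinical = clinical.assign(event=0)
        with pytest.raises(EstimationError):
            fit_cox(clinical, covariate)

    def test_separating_covariate_named_in_error(self):
        # covariate perfectly ordered with event times: monotone likelihood
        clinical = pd.DataFrame({
            "sample_id": [f"P{i}" for i in range(6)],
            "time": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            "event": [1, 1, 1, 1, 1, 1],
            "cohort": "c"})
        covariate = pd.Series([6.0, 5.0, 4.0, 3.0, 2.0, 1.0],
                              index=clinical["sample_id"], name="riskgene")
        with pytest.raises(ConvergenceError, match="riskgene"):
            fit_cox(clinical, covariate)

    def test_misaligned_covariates_rejected(self, survival_frame):
        clinical, covariate = survival_frame
        with pytest.raises(AlignmentError):
            fit_cox(clinical, covariate.iloc[:3])

    def test_ci_brackets_hr(self, survival_frame):
        clinical, covariate = survival_frame
        f = fit_cox(clinical, covariate)
        assert f.ci_low[0] < f.hazard_ratios[0] < f.ci_high[0]
        assert np.isclose(f.hazard_ratios[0], np.exp(f.coefficients[0]))


class TestPerCohortHr:
    def test_single_cohort_matches_fit_cox(self, small_cohort):
        c = small_cohort
        tab = per_cohort_hr(c.clinical, c.expression, gene="CD274")
        assert len(tab) == 1
        cov = c.expression.loc["CD274", c.sample_ids]
        cov.name = "CD274"
        f = fit_cox(c.clinical, cov)
        assert np.isclose(tab["hr"].iloc[0], f.hazard_ratios[0])

    def test_duplicated_cohorts_give_identical_rows(self, small_cohort):
        c = small_cohort
        cl2 = c.clinical.assign(cohort="copy1")
        cl3 = c.clinical.assign(cohort="copy2")
        tab = per_cohort_hr(pd.concat([cl2, cl3], ignore_index=True),
                            c.expression, gene="CD274")
        assert len(tab) == 2
        np.testing.assert_allclose(tab["hr"].iloc[0], tab["hr"].iloc[1])

    def test_failing_cohort_skipped_not_fatal(self, small_cohort, caplog):
        c = small_cohort
        dead = c.clinical.iloc[:10].assign(cohort="noevents", event=0)
        cl = pd.concat([c.clinical, dead], ignore_index=True)
        with caplog.at_level("WARNING"):
            tab = per_cohort_hr(cl, c.expression, gene="CD274")
        assert set(tab["cohort"]) == {"cohort1"}
        assert "noevents" in caplog.text

    def test_recovers_generating_beta(self, default_params):
        p = default_params.with_(beta_ctl=0.0, beta_pdl1=-0.3, seed=31,
                                 n_samples=400)
        c = generate_cohort(p)
        tab = per_cohort_hr(c.clinical, c.expression, gene="CD274")
        assert abs(tab["coef"].iloc[0] - (-0.3)) <= 3 * tab["se"].iloc[0]


class TestHrConcordance:
    def _table(self, hrs, cohorts=None):
        cohorts = cohorts or [f"c{i}" for i in range(len(hrs))]
        return pd.DataFrame({"cohort": cohorts, "hr": hrs})

    def test_self_correlation_is_one(self):
        t = self._table([0.8, 1.1, 0.9, 1.3, 0.7])
        r, _ = hr_concordance(t, t)
        assert np.isclose(r, 1.0)

    def test_antisymmetry(self):
        a = self._table([0.8, 1.1, 0.9, 1.3, 0.7])
        b = self._table([2.0 - h for h in [0.8, 1.1, 0.9, 1.3, 0.7]])
        r, _ = hr_concordance(a, b)
        assert np.isclose(r, -1.0)

    def test_closed_form_pearson(self):
        hrs_a = [0.7, 0.85, 1.0, 1.2, 0.9]
        hrs_b = [0.75, 0.95, 0.88, 1.3, 1.0]
        a, b = self._table(hrs_a), self._table(hrs_b)
        x, y = np.array(hrs_a), np.array(hrs_b)
        expected = (np.sum((x - x.mean()) * (y - y.mean()))
                    / np.sqrt(np.sum((x - x.mean()) ** 2)
                              * np.sum((y - y.mean()) ** 2)))
        r, _ = hr_concordance(a, b)
        assert abs(r - expected) < 1e-12

    def test_mismatched_cohorts_rejected(self):
        a = self._table([1.0, 1.1, 0.9])
        b = self._table([1.0, 1.1, 0.9], cohorts=["x", "y", "z"])
        with pytest.raises(AlignmentError):
            hr_concordance(a, b)


class TestMetaFixedEffects:
    def test_single_study_identity(self):
        m = meta_fixed_effects([-0.1], [0.05])
        assert np.isclose(m.pooled_log_hr, -0.1)
        assert np.isclose(m.pooled_se, 0.05)

    def test_replication_shrinks_se_by_sqrt_k(self):
        m1 = meta_fixed_effects([0.2], [0.1])
        m4 = meta_fixed_effects([0.2] * 4, [0.1] * 4)
        assert np.isclose(m4.pooled_log_hr, m1.pooled_log_hr)
        assert np.isclose(m4.pooled_se, m1.pooled_se / 2.0)

    def test_hand_computed_example(self):
        m = meta_fixed_effects([0.0, 0.2], [0.1, 0.2])
        assert np.isclose(m.pooled_log_hr, 0.04)
        assert np.isclose(m.pooled_se, 125 ** -0.5)

    def test_reorder_and_merge_invariance(self):
        b, se = [0.1, -0.2, 0.3], [0.1, 0.2, 0.3]
        m1 = meta_fixed_effects(b, se)
        m2 = meta_fixed_effects(b[::-1], se[::-1])
        assert np.isclose(m1.pooled_log_hr, m2.pooled_log_hr)
        # two identical studies == one study with se/sqrt(2)
        m3 = meta_fixed_effects([0.1, 0.1, -0.2], [0.2, 0.2, 0.3])
        m4 = meta_fixed_effects([0.1, -0.2], [0.2 / np.sqrt(2), 0.3])
        assert np.isclose(m3.pooled_log_hr, m4.pooled_log_hr)
        assert np.isclose(m3.pooled_se, m4.pooled_se)

    def test_pooled_within_study_range(self):
        m = meta_fixed_effects([-0.3, 0.1, 0.5], [0.1, 0.1, 0.4])
        assert min(-0.3, 0.1, 0.5) <= m.pooled_log_hr <= max(-0.3, 0.1, 0.5)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValidationError):
            meta_fixed_effects([0.1], [0.0])

    def test_agrees_with_statsmodels(self):
        from statsmodels.stats.meta_analysis import combine_effects
        b = np.array([0.05, -0.2, 0.12, 0.3])
        se = np.array([0.1, 0.15, 0.08, 0.2])
        m = meta_fixed_effects(b, se)
        res = combine_effects(b, se ** 2)
        frame = res.summary_frame()
        assert np.isclose(m.pooled_log_hr,
                          frame.loc["fixed effect", "eff"], rtol=1e-10)


class TestKmLogrank:
    def test_hand_product_limit(self):
        cl = pd.DataFrame({"sample_id": ["a", "b", "c"],
                           "time": [1.0, 1.5, 2.0],
                           "event": [1, 0, 1], "cohort": "c"})
        curve = km_curve(cl)
        def s_at(t):
            return curve.survival[np.searchsorted(curve.times, t, "right") - 1]
        assert np.isclose(s_at(0.0), 1.0)
        assert np.isclose(s_at(1.2), 2.0 / 3.0)
        assert np.isclose(s_at(1.9), 2.0 / 3.0)
        assert np.isclose(s_at(2.0), 0.0)

    def test_no_events_curve_stays_at_one(self):
        cl = pd.DataFrame({"sample_id": ["a", "b"], "time": [1.0, 2.0],
                           "event": [0, 0], "cohort": "c"})
        curve = km_curve(cl)
        assert np.all(curve.survival == 1.0)

    def test_curve_monotone_from_one(self, small_cohort):
        curve = km_curve(small_cohort.clinical)
        assert curve.survival[0] == 1.0
        assert np.all(np.diff(curve.survival) <= 0)
        assert np.all(curve.survival >= 0)

    def test_logrank_group_against_itself_is_null(self, small_cohort):
        cl = small_cohort.clinical
        chi2, p = logrank(cl, cl.copy())
        assert chi2 < 1e-10
        assert p > 0.999

    def test_empty_group_rejected(self, small_cohort):
        with pytest.raises(ValidationError):
            logrank(small_cohort.clinical, small_cohort.clinical.iloc[:0])


class TestAdjustedCurves:
    def test_zero_coefficients_reduce_to_baseline(self, small_cohort):
        c = small_cohort
        ids = c.sample_ids
        cov = pd.DataFrame({
            "CD8A": c.expression.loc["CD8A", ids].to_numpy(),
            "CD274": c.expression.loc["CD274", ids].to_numpy()}, index=ids)
        fit = fit_cox(c.clinical, cov)
        null = CoxFit(**{**fit.__dict__, "coefficients": np.zeros(2)})
        low, high = adjusted_curves(null, display="CD274")
        np.testing.assert_allclose(low.survival, high.survival)
        np.testing.assert_allclose(
            low.survival[1:], np.exp(-fit.baseline_cumhaz))

    def test_curves_monotone_from_one(self, small_cohort):
        c = small_cohort
        ids = c.sample_ids
        cov = pd.DataFrame({
            "CD8A": c.expression.loc["CD8A", ids].to_numpy(),
            "CD274": c.expression.loc["CD274", ids].to_numpy()}, index=ids)
        fit = fit_cox(c.clinical, cov)
        for curve in adjusted_curves(fit, display="CD274"):
            assert curve.survival[0] == 1.0
            assert np.all(np.diff(curve.survival) <= 0)

    def test_single_covariate_breslow_oracle(self, small_cohort):
        """S0(t)^exp(beta*x) matches an independent step-function oracle."""
        c = small_cohort
        cov = c.expression.loc["CD274", c.sample_ids]
        cov.name = "CD274"
        fit = fit_cox(c.clinical, cov)
        t = c.clinical["time"].to_numpy()
        d = c.clinical["event"].to_numpy()
        x = cov.to_numpy()
        beta = fit.coefficients[0]
        # independent Breslow baseline: H0(t) = sum_{t_j<=t} d_j / sum_risk w
        uts = np.sort(np.unique(t[d == 1]))
        h0 = np.cumsum([
            (d[t == ut].sum()) / np.exp(beta * x[t >= ut]).sum()
            for ut in uts])
        x_star = float(np.mean(x))
        expected = np.exp(-h0 * np.exp(beta * x_star))
        from reactivepdl1.survival import _curve_from_baseline
        curve = _curve_from_baseline(fit, beta * x_star, "m")
        np.testing.assert_allclose(curve.survival[1:], expected, rtol=1e-10)

    def test_zero_covariate_baseline_close_to_km(self, default_params):
        """exp(-H0) from a null-coefficient fit tracks the product-limit
        curve (they differ at second order in the per-time hazard)."""
        c = generate_cohort(default_params.with_(n_samples=150, seed=41))
        # Breslow baseline under beta=0: H0 increments = d_j / n_at_risk
        t = c.clinical["time"].to_numpy()
        d = c.clinical["event"].to_numpy()
        uts = np.sort(np.unique(t[d == 1]))
        h0 = np.cumsum([(d[t == ut].sum()) / (t >= ut).sum() for ut in uts])
        km = km_curve(c.clinical)
        def km_at(u):
            return km.survival[np.searchsorted(km.times, u, "right") - 1]
        breslow = np.exp(-h0)
        km_vals = np.array([km_at(u) for u in uts])
        assert np.all(np.abs(breslow - km_vals) < 0.02)
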