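"""Decline scoring, correlations, regression, prediction, mixed models, Fisher."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lingtract.exceptions import InputError, ValidationError
from lingtract.outcomes import (
    compare_correlations,
    contingency,
    decline_scores,
    evaluate_prediction,
    fisher_exact_2x2,
    fit_mixed_model,
    fit_regression,
    pearson_r,
    seizure_outcome_test,
    to_long,
)
from lingtract.synthetic import CohortSpec, make_cohort


class TestDeclineScores:
    def _cohort(self, pre, m4, m12):
        df = make_cohort(CohortSpec(n_subjects=len(pre), seed=0, n_missing_12mo=0)).df
        df["gnt_pre"] = pre
        df["gnt_4mo"] = m4
        df["gnt_12mo"] = m12
        return df

    def test_threshold_boundary(self):
        df = self._cohort([16, 16, 16], [12.0, 13.0, 12.0], [10.0, 15.0, np.nan])
        s = decline_scores(df)
        assert s.loc[0, "delta_4mo"] == -4 and bool(s.loc[0, "significant_4mo"])
        assert s.loc[1, "delta_4mo"] == -3 and not bool(s.loc[1, "significant_4mo"])
        assert pd.isna(s.loc[2, "delta_12mo"]) and pd.isna(s.loc[2, "significant_12mo"])


class TestPearson:
    def test_perfect_linearity(self):
        x = np.arange(10.0)
        r, p = pearson_r(x, 2 * x + 1)
        assert r == pytest.approx(1.0)

    def test_orthogonal_vectors_give_zero(self):
        x = np.array([1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        r, _ = pearson_r(x, y)
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_is_missing(self):
        r, p = pearson_r(np.ones(5), np.arange(5.0))
        assert math.isnan(r) and math.isnan(p)

    def test_pairwise_deletion(self):
        x = np.array([1.0, 2.0, 3.0, np.nan, 5.0])
        y = np.array([2.0, 4.0, 6.0, 1.0, 10.0])
        r, _ = pearson_r(x, y)
        assert r == pytest.approx(1.0)

    def test_planted_population_correlation_recovered(self):
        # closed form: r = b sd_x / sqrt(b^2 sd_x^2 + noise^2 + 1/12)
        # (the 1/12 is the variance of score rounding)
        spec = CohortSpec(
            n_subjects=500, effect_slope=1.3205, noise_sd=2.0, subject_sd=0.0,
            n_missing_12mo=0, seed=21,
        )
        b = spec.effect_slope / spec.volume_scale_mm3
        sd_x = spec.volume_sd_mm3
        r_pop = b * sd_x / math.sqrt((b * sd_x) ** 2 + spec.noise_sd**2 + 1 / 12)
        df = make_cohort(spec).df
        r, _ = pearson_r(df["v_surg_norm"], df["gnt_pre"] - df["gnt_4mo"])
        assert r == pytest.approx(r_pop, abs=0.05)


class TestCompareCorrelations:
    def test_identical_correlations(self):
        z, p = compare_correlations(0.5, 30, 0.5, 50)
        assert z == 0.0 and p == 1.0

    def test_large_difference_significant_and_matches_hand_formula(self):
        z, p = compare_correlations(0.9, 100, 0.0, 100)
        by_hand = (np.arctanh(0.9) - 0.0) / math.sqrt(1 / 97 + 1 / 97)
        assert z == pytest.approx(by_hand)
        assert p < 0.001

    def test_swapping_groups_negates_z(self):
        z1, p1 = compare_correlations(0.7, 40, 0.2, 60)
        z2, p2 = compare_correlations(0.2, 60, 0.7, 40)
        assert z2 == pytest.approx(-z1)
        assert p2 == pytest.approx(p1)

    def test_degenerate_r_rejected(self):
        with pytest.raises(InputError):
            compare_correlations(1.0, 30, 0.5, 30)


class TestFitRegression:
    def test_exact_linear_outcome_recovered_to_machine_precision(self):
        df = make_cohort(CohortSpec(n_subjects=40, seed=2, n_missing_12mo=0)).df
        # plant outcome as an exact linear function of the design
        coef = {
            "v_surg_norm": 0.002, "gnt_pre": -0.1, "age_years": 0.05,
            "onset_age_years": -0.02, "duration_years": 0.03, "education_level": 0.4,
            "fmri_li": 1.5,
        }
        y = 1.0 + sum(c * df[k] for k, c in coef.items())
        y += 0.7 * (df["sex"] == "m") + 0.9 * (df["surgery_type"] == "lesionectomy")
        df["gnt_4mo"] = df["gnt_pre"] - y
        fit = fit_regression(df, "v_surg_norm", timepoint="4mo")
        assert fit.r2 == pytest.approx(1.0, abs=1e-10)
        assert fit.params["v_surg_norm"] == pytest.approx(0.002, rel=1e-8)
        assert fit.params["const"] == pytest.approx(1.0, rel=1e-6)

    def test_duplicated_predictor_is_rank_deficiency_error(self):
        df = make_cohort(CohortSpec(n_subjects=30, seed=2, n_missing_12mo=0)).df
        df["v_copy"] = df["v_surg_norm"]
        with pytest.raises(ValidationError, match="v_copy"):
            fit_regression(
                df, "v_surg_norm", timepoint="4mo",
                covariates=("gnt_pre", "age_years", "v_copy"),
            )

    def test_r2_never_decreases_with_added_regressor(self):
        df = make_cohort(CohortSpec(n_subjects=40, seed=3, n_missing_12mo=0)).df
        base: tuple = ()
        r2_prev = -1.0
        for cov in [(), ("gnt_pre",), ("gnt_pre", "age_years"),
                    ("gnt_pre", "age_years", "fmri_li")]:
            fit = fit_regression(df, "v_surg_norm", timepoint="4mo", covariates=cov)
            assert fit.r2 >= r2_prev - 1e-12
            r2_prev = fit.r2

    def test_degrees_of_freedom_match_cohort_scale(self):
        # n = 20 with the eight standard covariates + predictor: F(9, 10)
        df = make_cohort(CohortSpec(n_subjects=20, seed=4, n_missing_12mo=0)).df
        fit = fit_regression(df, "v_surg_norm", timepoint="4mo")
        assert (fit.df_model, fit.df_resid) == (9, 10)

    def test_too_few_complete_cases_rejected(self):
        df = make_cohort(CohortSpec(n_subjects=8, seed=5, n_missing_12mo=0)).df
        with pytest.raises(InputError):
            fit_regression(df, "v_surg_norm", timepoint="4mo")


class TestEvaluatePrediction:
    def test_published_style_contingency_tables(self):
        # 4-month: TP 6, FP 1, FN 0, TN 13 -> 100% sensitivity, 13/14 = 93%
        pred = [True] * 6 + [True] + [False] * 13
        act = [True] * 6 + [False] + [False] * 13
        ev = contingency(pred, act)
        assert (ev.tp, ev.fp, ev.fn, ev.tn) == (6, 1, 0, 13)
        assert ev.sensitivity_pct == pytest.approx(100.0)
        assert ev.specificity_pct == pytest.approx(100 * 13 / 14)
        assert ev.rounded() == (100, 93)

    def test_perfect_predictor(self):
        df = make_cohort(
            CohortSpec(n_subjects=30, effect_slope=3.0, noise_sd=0.0, subject_sd=0.0,
                       n_missing_12mo=0, seed=6)
        ).df
        actual = (df["gnt_pre"] - df["gnt_4mo"]) >= 4
        ev = contingency(actual, actual)
        assert ev.sensitivity_pct == 100.0 and ev.specificity_pct == 100.0

    def test_invariant_to_subject_order(self):
        rng = np.random.default_rng(0)
        pred = rng.random(50) < 0.4
        act = rng.random(50) < 0.3
        ev1 = contingency(pred, act)
        perm = rng.permutation(50)
        ev2 = contingency(pred[perm], act[perm])
        assert (ev1.tp, ev1.fp, ev1.fn, ev1.tn) == (ev2.tp, ev2.fp, ev2.fn, ev2.tn)

    def test_no_actual_decliners_gives_missing_sensitivity(self):
        ev = contingency([False, True], [False, False])
        assert math.isnan(ev.sensitivity_pct)

    def test_in_sample_prediction_on_strong_effect(self):
        df = make_cohort(
            CohortSpec(n_subjects=20, effect_slope=1.5, noise_sd=0.25, subject_sd=0.25,
                       n_missing_12mo=0, seed=7, volume_sd_mm3=3000.0)
        ).df
        fit = fit_regression(df, "v_surg_norm", timepoint="4mo")
        ev = evaluate_prediction(fit)
        assert ev.n == 20
        assert ev.sensitivity_pct == pytest.approx(100.0)

    def test_loo_prediction_runs(self):
        df = make_cohort(
            CohortSpec(n_subjects=25, effect_slope=2.0, noise_sd=0.5, subject_sd=0.0,
                       n_missing_12mo=0, seed=8)
        ).df
        fit = fit_regression(df, "v_surg_norm", timepoint="4mo")
        ev = evaluate_prediction(fit, loo=True)
        assert ev.n == 25


class TestMixedModel:
    def test_full_model_likelihood_dominates_null(self):
        for seed in (1, 2, 3):
            df = make_cohort(CohortSpec(n_subjects=60, seed=seed)).df
            mm = fit_mixed_model(to_long(df, ("v_surg_norm",)), "v_surg_norm")
            assert mm.llf >= mm.llf_null - 1e-6
            assert mm.random_intercept_var >= 0
            assert 0.0 <= mm.marginal_r2 <= 1.0

    def test_strong_effect_detected(self):
        df = make_cohort(
            CohortSpec(n_subjects=100, effect_slope=2.0, noise_sd=1.0, subject_sd=1.0,
                       n_missing_12mo=0, seed=9)
        ).df
        mm = fit_mixed_model(to_long(df, ("v_surg_norm",)), "v_surg_norm")
        assert mm.p < 0.001
        assert mm.marginal_r2 > 0.3

    def test_time_point_offset_recovered(self):
        df = make_cohort(
            CohortSpec(n_subjects=500, effect_slope=1.0, noise_sd=1.0, subject_sd=1.0,
                       extra_decline_12mo=3.0, n_missing_12mo=0, seed=10)
        ).df
        mm = fit_mixed_model(to_long(df, ("v_surg_norm",)), "v_surg_norm")
        assert mm.fe_params["time_12mo"] == pytest.approx(3.0, rel=0.10)

    def test_single_row_subjects_fall_back_to_ols_with_warning(self):
        df = make_cohort(CohortSpec(n_subjects=40, seed=11, n_missing_12mo=0)).df
        df["gnt_12mo"] = np.nan  # only 4-month rows remain
        with pytest.warns(UserWarning, match="degenerates to OLS"):
            mm = fit_mixed_model(to_long(df, ("v_surg_norm",)), "v_surg_norm")
        assert mm.used_ols_fallback
        assert mm.random_intercept_var == 0.0


class TestFisherExact:
    def test_no_association(self):
        assert fisher_exact_2x2([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_matches_hypergeometric_enumeration_oracle(self):
        # brute force: sum hypergeometric probabilities of all tables with
        # the same margins whose probability <= that of the observed table
        def brute_force(table):
            (a, b), (c, d) = table
            n = a + b + c + d
            row1, col1 = a + b, a + c
            p_obs = stats.hypergeom.pmf(a, n, row1, col1)
            total = 0.0
            for aa in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
                p = stats.hypergeom.pmf(aa, n, row1, col1)
                if p <= p_obs * (1 + 1e-9):
                    total += p
            return total

        for table in ([[10, 0], [0, 10]], [[8, 2], [3, 7]], [[1, 9], [5, 5]]):
            assert fisher_exact_2x2(table) == pytest.approx(brute_force(table), rel=1e-9)

    def test_transpose_symmetry(self):
        t = np.array([[7, 2], [3, 8]])
        assert fisher_exact_2x2(t) == pytest.approx(fisher_exact_2x2(t.T))

    def test_empty_margin_gives_one(self):
        assert fisher_exact_2x2([[0, 0], [3, 7]]) == 1.0

    def test_seizure_outcome_on_synthetic_cohort(self):
        cohort = make_cohort(CohortSpec(seed=12))
        p = seizure_outcome_test(cohort, timepoint="4mo")
        assert 0.0 <= p <= 1.0
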