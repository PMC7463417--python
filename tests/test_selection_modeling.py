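"""Two-step feature selection, ROC/Youden, DeLong, the combined logistic
model and its calibration test, against closed forms and library oracles."""

import numpy as np
import pandas as pd
import pytest

from pettex.selection_modeling import (
    default_category_map,
    delong_compare,
    fit_prediction_probability,
    hosmer_lemeshow,
    roc_analysis,
    select_per_category,
    univariate_filter,
)
from pettex.stats_core import mann_whitney_u


def _labels(n_pos, n_neg):
    return np.array(["nonCR"] * n_pos + ["CR"] * n_neg)


class TestUnivariateFilter:
    def test_identical_feature_eliminated_and_separated_feature_kept(self):
        rng = np.random.default_rng(0)
        labels = _labels(10, 20)
        df = pd.DataFrame(
            {
                "flat": np.ones(30),
                "same": rng.normal(size=30),
                "separated": np.r_[np.ones(10) * 10, np.zeros(20)] + rng.normal(0, 0.01, 30),
            }
        )
        survivors, table = univariate_filter(df, labels)
        assert "separated" in survivors
        assert "flat" not in survivors
        assert table.loc["flat", "p_value"] == 1.0
        assert table.loc["flat", "warning"] == "constant feature"

    def test_selection_invariant_to_column_order_and_monotone_transform(self):
        rng = np.random.default_rng(1)
        labels = _labels(10, 20)
        a = np.r_[rng.normal(3, 1, 10), rng.normal(0, 1, 20)]
        b = rng.normal(size=30)
        df1 = pd.DataFrame({"a": a, "b": b})
        df2 = pd.DataFrame({"b": b, "a": np.exp(a)})  # reorder + monotone map
        s1, t1 = univariate_filter(df1, labels)
        s2, t2 = univariate_filter(df2, labels)
        assert set(s1) == set(s2)
        assert t1.loc["a", "p_value"] == pytest.approx(t2.loc["a", "p_value"])

    def test_default_cohort_retains_core_features(self, default_cohort):
        from pettex.texture_features import extract_feature_table

        feats = extract_feature_table(default_cohort)
        labels = [r.response for r in default_cohort]
        survivors, _ = univariate_filter(feats.drop(columns=["suvmax", "mtv_mm3"]), labels)
        # the cohort's built-in effects: size and heterogeneity retain their
        # features reliably; the uptake-intensity channel is represented by
        # at least one of its features (which one fluctuates at n = 30, as
        # it would in a real cohort of this size)
        for name in ("entropy", "volume_mm3", "max_diameter_mm"):
            assert name in survivors
        assert any(f in survivors for f in ("mean", "p50", "p75", "p90", "maximum"))


class TestSelectPerCategory:
    def test_tie_under_non_normality_prefers_percentile(self):
        p = {"mean": 0.028, "p50": 0.028, "volume_mm3": 0.006}
        cats = {"mean": "uptake_intensity", "p50": "uptake_intensity",
                "volume_mm3": "tumor_size"}
        normality = {"mean": 0.001, "p50": 0.001}  # grey levels not normal
        sel = select_per_category(p, cats, normality)
        assert sel["uptake_intensity"] == "p50"
        assert sel["tumor_size"] == "volume_mm3"

    def test_tie_under_normality_prefers_moment(self):
        p = {"mean": 0.03, "p50": 0.03}
        cats = {"mean": "uptake_intensity", "p50": "uptake_intensity"}
        sel = select_per_category(p, cats, {"mean": 0.8, "p50": 0.8})
        assert sel["uptake_intensity"] == "mean"

    def test_lowest_p_wins_within_category(self):
        p = {"entropy": 0.007, "entropy_glcm10": 0.015, "energy_glcm10": 0.049}
        cats = {k: "heterogeneity" for k in p}
        assert select_per_category(p, cats)["heterogeneity"] == "entropy"

    def test_single_survivor_selected_regardless_of_p(self):
        sel = select_per_category({"sd": 0.049}, {"sd": "intensity_distribution"})
        assert sel == {"intensity_distribution": "sd"}

    def test_default_map_covers_all_features(self):
        from pettex.texture_features import CT_FEATURES, PET_FEATURES

        names = ["suvmax", "mtv_mm3"] + PET_FEATURES + CT_FEATURES
        mapping = default_category_map(names)
        assert set(mapping) == set(names)
        assert mapping["suvmax"] == "excluded"
        assert mapping["mtv_mm3"] == "excluded"  # volume is the size candidate
        assert mapping["p50"] == "uptake_intensity"
        assert mapping["ct_max_frequency"] == "intensity_distribution"
        assert mapping["volume_mm3"] == "tumor_size"
        assert mapping["entropy"] == "heterogeneity"
        assert mapping["energy_glcm12"] == "heterogeneity"


class TestRocAnalysis:
    def test_perfect_separation(self):
        res = roc_analysis([10, 11, 12, 1, 2, 3], _labels(3, 3))
        assert res.auc == 1.0
        assert res.sensitivity == 1.0 and res.specificity == 1.0
        # strict ">" call rule: any cutoff in [3, 10) separates perfectly
        assert 3 <= res.cutoff < 10

    def test_null_auc_near_half(self):
        rng = np.random.default_rng(2)
        res = roc_analysis(rng.normal(size=400), _labels(200, 200))
        assert abs(res.auc - 0.5) < 0.08

    def test_auc_equals_u_statistic_identity(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            x = rng.normal(1, 1, size=12)
            y = rng.normal(0, 1, size=17)
            values = np.r_[x, y]
            labels = _labels(12, 17)
            auc_raw = mann_whitney_u(x, y).statistic / (12 * 17)
            res = roc_analysis(values, labels)
            assert res.auc == pytest.approx(max(auc_raw, 1 - auc_raw), abs=1e-12)

    def test_lower_is_positive_orientation(self):
        res = roc_analysis([1, 2, 3, 10, 11, 12], _labels(3, 3))
        assert res.direction == "lower-is-positive"
        assert res.auc == 1.0
        assert res.sensitivity == 1.0 and res.specificity == 1.0

    def test_accuracy_matches_confusion_counts_at_cutoff(self):
        rng = np.random.default_rng(4)
        values = rng.normal(size=30) + np.r_[np.ones(10), np.zeros(20)]
        labels = _labels(10, 20)
        res = roc_analysis(values, labels)
        calls = values > res.cutoff
        tp = int((calls & (labels == "nonCR")).sum())
        tn = int((~calls & (labels == "CR")).sum())
        assert res.accuracy == pytest.approx((tp + tn) / 30)

    def test_one_class_absent_rejected(self):
        with pytest.raises(ValueError):
            roc_analysis([1, 2, 3], np.array(["CR", "CR", "CR"]))


class TestDelong:
    def test_identical_markers_p_one(self):
        rng = np.random.default_rng(5)
        v = rng.normal(size=30) + np.r_[np.ones(10), np.zeros(20)]
        res = delong_compare(v, v, _labels(10, 20))
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_monotone_transform_gives_identical_aucs(self):
        rng = np.random.default_rng(6)
        v = rng.lognormal(size=30) + np.r_[np.ones(10), np.zeros(20)]
        res = delong_compare(v, 2.0 * v, _labels(10, 20))
        assert res.p_value == 1.0

    def test_null_calibration_exchangeable_markers(self):
        rng = np.random.default_rng(7)
        n_reps, rejections = 500, 0
        labels = _labels(20, 20)
        for _ in range(n_reps):
            signal = np.r_[rng.normal(0.8, 1, 20), rng.normal(0, 1, 20)]
            a = signal + rng.normal(0, 1, 40)
            b = signal + rng.normal(0, 1, 40)  # exchangeable with a
            if delong_compare(a, b, labels).p_value < 0.05:
                rejections += 1
        rate = rejections / n_reps
        assert abs(rate - 0.05) < 3.3 * np.sqrt(0.05 * 0.95 / n_reps)


class TestLogisticModel:
    def test_single_binary_predictor_recovers_table_log_odds(self):
        # balanced 2x2: coefficient = log OR of the table
        x = np.r_[np.ones(40), np.zeros(40)]
        y = np.array(["nonCR"] * 30 + ["CR"] * 10 + ["nonCR"] * 10 + ["CR"] * 30)
        df = pd.DataFrame({"x": x})
        model = fit_prediction_probability(df, y, predictors=["x"])
        log_or = np.log((30 * 30) / (10 * 10))
        assert model.converged
        assert model.coefficients[0] == pytest.approx(log_or, rel=1e-6)
        assert model.intercept == pytest.approx(np.log(10 / 30), rel=1e-6)

    def test_matches_statsmodels_mle(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(8)
        X = rng.normal(size=(200, 3))
        eta = 0.5 + X @ np.array([1.0, -0.5, 2.0])
        y01 = rng.random(200) < 1 / (1 + np.exp(-eta))
        labels = np.where(y01, "nonCR", "CR")
        df = pd.DataFrame(X, columns=["a", "b", "c"])
        model = fit_prediction_probability(df, labels, predictors=["a", "b", "c"])
        ref = sm.Logit(y01.astype(float), sm.add_constant(X)).fit(disp=0)
        assert model.intercept == pytest.approx(ref.params[0], abs=1e-6)
        np.testing.assert_allclose(model.coefficients, ref.params[1:], atol=1e-6)
        assert model.log_likelihood == pytest.approx(ref.llf, abs=1e-8)

    def test_parameter_recovery_within_three_se(self):
        rng = np.random.default_rng(9)
        true_beta = np.array([1.0, -0.5, 2.0])
        X = rng.normal(size=(2000, 3))
        eta = X @ true_beta
        labels = np.where(rng.random(2000) < 1 / (1 + np.exp(-eta)), "nonCR", "CR")
        df = pd.DataFrame(X, columns=["a", "b", "c"])
        model = fit_prediction_probability(df, labels, predictors=["a", "b", "c"])
        # observed-information standard errors
        p = model.probabilities
        Xd = np.column_stack([np.ones(2000), X])
        H = Xd.T @ (Xd * (p * (1 - p))[:, None])
        se = np.sqrt(np.diag(np.linalg.inv(H)))[1:]
        np.testing.assert_array_less(np.abs(model.coefficients - true_beta), 3 * se)

    def test_null_predictors_give_chance_level_roc(self):
        rng = np.random.default_rng(10)
        df = pd.DataFrame(rng.normal(size=(300, 2)), columns=["a", "b"])
        labels = np.where(rng.random(300) < 0.4, "nonCR", "CR")
        model = fit_prediction_probability(df, labels, predictors=["a", "b"])
        res = roc_analysis(model.probabilities, labels)
        assert abs(res.auc - 0.5) < 0.1

    def test_perfect_separation_flagged_but_probabilities_returned(self):
        df = pd.DataFrame({"x": np.r_[np.ones(10), np.zeros(10)]})
        labels = _labels(10, 10)
        model = fit_prediction_probability(df, labels, predictors=["x"])
        assert not model.converged
        assert model.warning is not None
        assert np.all((model.probabilities > 0) & (model.probabilities < 1))
        assert roc_analysis(model.probabilities, labels).auc == 1.0


class TestHosmerLemeshow:
    def test_published_chi_square_reproduces_p(self):
        # independent route to the same tail probability the model reports
        from pettex.stats_core import chi2_upper_tail

        assert chi2_upper_tail(9.727, 10 - 2) == pytest.approx(0.285, abs=5e-4)

    def test_calibrated_fitted_model_near_nominal_rejection(self):
        """df = groups - 2 presumes in-sample fitted probabilities, so the
        null simulation fits the model it tests on each replicate."""
        rng = np.random.default_rng(11)
        n_reps, rejections = 300, 0
        for _ in range(n_reps):
            X = rng.normal(size=(200, 2))
            eta = -0.5 + X @ np.array([1.0, 0.7])
            labels = np.where(rng.random(200) < 1 / (1 + np.exp(-eta)), "nonCR", "CR")
            df = pd.DataFrame(X, columns=["a", "b"])
            model = fit_prediction_probability(df, labels, predictors=["a", "b"])
            if hosmer_lemeshow(model.probabilities, labels).p_value < 0.05:
                rejections += 1
        rate = rejections / n_reps
        assert abs(rate - 0.05) < 3.5 * np.sqrt(0.05 * 0.95 / n_reps)

    def test_miscalibrated_probabilities_rejected(self):
        rng = np.random.default_rng(12)
        hits = 0
        for _ in range(20):
            p = rng.uniform(0.05, 0.95, size=2000)
            labels = np.where(rng.random(2000) < p, "nonCR", "CR")
            if hosmer_lemeshow(p**2, labels).p_value < 0.05:
                hits += 1
        assert hits >= 18

    def test_df_is_groups_minus_two(self):
        rng = np.random.default_rng(13)
        p = rng.uniform(0.1, 0.9, size=100)
        labels = np.where(rng.random(100) < p, "nonCR", "CR")
        assert hosmer_lemeshow(p, labels, n_groups=10).df == 8
        assert hosmer_lemeshow(p, labels, n_groups=6).df == 4


class TestCombinedModelBeatsSingles:
    def test_combined_auc_usually_beats_best_single(self):
        """With all four effects active the combined model's in-sample AUC
        exceeds the best single feature's in most replicate cohorts."""
        rng = np.random.default_rng(14)
        wins = 0
        n_reps = 30
        for _ in range(n_reps):
            n = 60
            y = np.r_[np.ones(20), np.zeros(40)]
            suv = rng.lognormal(0, 0.5, n) * (1 + 0.8 * y)
            ent = rng.normal(6, 1, n) + 1.0 * y
            vol = rng.lognormal(10, 0.8, n) * (1 + 2 * y)
            intest = (rng.random(n) < (0.3 + 0.4 * y)).astype(float)
            labels = np.where(y == 1, "nonCR", "CR")
            df = pd.DataFrame({"suvmax": suv, "entropy": ent, "volume_mm3": vol,
                               "intestinal_involvement": intest})
            model = fit_prediction_probability(df, labels)
            combined = roc_analysis(model.probabilities, labels).auc
            best_single = max(roc_analysis(df[c].to_numpy(), labels).auc for c in df)
            wins += combined > best_single
        assert wins > n_reps / 2
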