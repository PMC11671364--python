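"""Screening model, threshold calibration, stage table, age check."""

import numpy as np
import pandas as pd
import pytest

from urometab.screening import (TrainConfig, age_confound_check, calibrate,
                                calibrate_threshold, detection_rate_by_stage,
                                train_screening_model)
from urometab.evaluation import roc_auc


def gaussian_clouds(n=200, delta=4.0, p=5, seed=0):
    rng = np.random.default_rng(seed)
    X0 = rng.normal(0, 1, size=(n // 2, p))
    X1 = rng.normal(delta / np.sqrt(p), 1, size=(n // 2, p))
    X = pd.DataFrame(np.vstack([X0, X1]), columns=[f"f{i}" for i in range(p)],
                     index=[f"S{i}" for i in range(n)])
    y = np.repeat([0, 1], n // 2)
    return X, y


class TestTrainScreeningModel:
    def test_separated_clouds_reach_high_cv_auc(self):
        X, y = gaussian_clouds(n=200, delta=4.0)
        model = train_screening_model(X, y, TrainConfig(seed=1))
        assert model.cv_best_auc >= 0.99
        held, yh = gaussian_clouds(n=200, delta=4.0, seed=99)
        assert roc_auc(model.scores(held), yh).auc >= 0.99

    def test_permuted_labels_stay_near_half(self):
        X, y = gaussian_clouds(n=160, delta=3.0, seed=2)
        rng = np.random.default_rng(7)
        aucs = []
        for rep in range(5):
            yp = rng.permutation(y)
            model = train_screening_model(
                X, yp, TrainConfig(cv_repeats=2, seed=rep))
            aucs.append(model.cv_best_auc)
        # null binomial band around 0.5 for the Mann-Whitney statistic
        n1 = n0 = 80
        sd = np.sqrt((n0 + n1 + 1) / (12 * n0 * n1))
        assert all(abs(a - 0.5) < 3 * sd for a in aucs)

    def test_scoring_is_deterministic(self):
        X, y = gaussian_clouds(n=120, delta=2.0, seed=3)
        model = train_screening_model(X, y, TrainConfig(cv_repeats=2, seed=5))
        s1 = model.scores(X)
        s2 = model.scores(X.copy())
        pd.testing.assert_series_equal(s1, s2)

    def test_linear_kernel_score_shift_is_predictable(self):
        X, y = gaussian_clouds(n=120, delta=3.0, seed=4)
        model = train_screening_model(X, y, TrainConfig(cv_repeats=2, seed=5))
        w = model.estimator.coef_.ravel()
        shifted = X.copy()
        shifted.iloc[0] += 1.0
        ds = model.scores(shifted).iloc[0] - model.scores(X).iloc[0]
        assert ds == pytest.approx(w.sum(), rel=1e-6)

    def test_too_few_samples_per_fold_rejected(self):
        X, y = gaussian_clouds(n=8, delta=2.0)
        with pytest.raises(ValueError, match="fewer than cv_folds"):
            train_screening_model(X, y, TrainConfig(cv_folds=5))


class TestCalibrateThreshold:
    def test_worked_example(self):
        thr, achieved = calibrate_threshold([0.1, 0.2, 0.3, 0.9], 0.75)
        assert 0.3 < thr <= 0.9
        assert achieved == pytest.approx(0.75)

    def test_target_one_clears_all_controls(self):
        thr, achieved = calibrate_threshold([0.5, 1.5, -0.2], 1.0)
        assert thr > 1.5
        assert achieved == 1.0

    def test_tied_controls_step_past_the_tie(self):
        thr, achieved = calibrate_threshold([2.0] * 10, 0.8)
        assert thr > 2.0
        assert achieved == 1.0

    def test_unreachable_target_warns(self):
        with pytest.warns(UserWarning, match="unreachable"):
            thr, achieved = calibrate_threshold([0.1, 0.2], 0.99)
        assert thr > 0.2 and achieved == 1.0

    @pytest.mark.parametrize("target", [0.95, 0.99])
    def test_fresh_control_specificity_matches_target(self, target):
        """Thresholds set on 500 controls generalize to 2000 fresh controls.

        The threshold steps just past the (n-k)th order statistic of the
        calibration controls, so its true specificity is Beta(n-k, k+1)
        distributed and the fresh-control count below threshold follows the
        exact Beta-Binomial compound; the 95% band of that compound is the
        correctly calibrated acceptance region.
        """
        from scipy.stats import betabinom
        n, m = 500, 2000
        k = int(np.floor((1 - target) * n))
        rng = np.random.default_rng(12)
        thr, achieved = calibrate_threshold(rng.normal(0, 1, size=n), target)
        assert achieved >= target  # guaranteed on calibration data
        below = int((rng.normal(0, 1, size=m) < thr).sum())
        lo = betabinom.ppf(0.025, m, n - k, k + 1)
        hi = betabinom.ppf(0.975, m, n - k, k + 1)
        assert lo <= below <= hi


class TestDetectionRateByStage:
    def _meta(self, stages, groups=None):
        n = len(stages)
        return pd.DataFrame({
            "group": groups or ["LC"] * n,
            "stage": stages,
            "age": [60] * n,
            "sex": ["F"] * n,
        }, index=[f"S{i}" for i in range(n)])

    def test_saturated_detection(self):
        meta = self._meta(["I", "II", "III", "IV"])
        scores = pd.Series([5.0] * 4, index=meta.index)
        tab = detection_rate_by_stage(scores, 0.0, meta)
        assert (tab.loc[["I", "II", "III", "IV"], "rate"] == 1.0).all()
        assert tab.loc["overall", "n"] == 4

    def test_empty_stratum_is_nan_not_zero(self):
        meta = self._meta(["I", "I"])
        scores = pd.Series([1.0, -1.0], index=meta.index)
        tab = detection_rate_by_stage(scores, 0.0, meta)
        assert np.isnan(tab.loc["IV", "rate"])
        assert tab.loc["I", "rate"] == pytest.approx(0.5)

    def test_non_cancer_samples_excluded(self):
        meta = self._meta(["I", "not-applicable"], groups=["LC", "HC"])
        scores = pd.Series([1.0, 1.0], index=meta.index)
        tab = detection_rate_by_stage(scores, 0.0, meta)
        assert tab.loc["overall", "n"] == 1

    def test_binomial_ci_brackets_rate(self):
        meta = self._meta(["II"] * 40)
        detected = pd.Series([1.0] * 30 + [-1.0] * 10, index=meta.index)
        tab = detection_rate_by_stage(detected, 0.0, meta)
        row = tab.loc["II"]
        assert row["ci_lower"] < row["rate"] < row["ci_upper"]


class TestAgeConfoundCheck:
    def test_identity_and_anti_identity(self):
        ages = np.arange(10.0, 60.0)
        assert age_confound_check(ages, ages)[0] == pytest.approx(1.0)
        assert age_confound_check(-ages, ages)[0] == pytest.approx(-1.0)

    def test_independent_scores_have_negligible_correlation(self):
        rng = np.random.default_rng(5)
        hits = 0
        for rep in range(10):
            r, _ = age_confound_check(rng.normal(size=400), rng.normal(size=400))
            hits += abs(r) < 0.1
        assert hits >= 9

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            age_confound_check(np.ones(10), np.arange(10.0))


class TestEndToEndCalibration:
    def test_validation_specificity_near_target(self, preprocessed_marker_cohort):
        X, meta, truth, _ = preprocessed_marker_cohort
        disc = meta.index[meta["cohort"] == "discovery"]
        val = meta.index[meta["cohort"] == "validation"]
        y = meta["group"].isin(["LC", "GC", "CRC"]).astype(int)
        feats = truth.planted_feature_ids()
        model = train_screening_model(X.loc[disc, feats], y.loc[disc],
                                      TrainConfig(cv_repeats=2, seed=2))
        cal = calibrate(model, X.loc[disc][~y.loc[disc].astype(bool)][feats], 0.9)
        assert cal.achieved_specificity >= 0.9
        val_controls = X.loc[val][~y.loc[val].astype(bool)]
        spec = (model.scores(val_controls) < cal.threshold).mean()
        assert spec > 0.75  # small validation arm; generous check
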