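"""Pan-cancer screening model: balanced SVM with a specificity-anchored cutoff.

The scorer is a class-weight-balanced support-vector machine over the
selected metabolite panel, tuned by repeated stratified k-fold
cross-validation (default 5 folds x 5 repeats, maximising mean AUC) and
refitted on the full discovery set.  The operating point is set on
discovery control scores only: the decision threshold is the smallest
value whose control exceedance fraction stays at or below 1 - target
specificity, which makes "specificity > 99%" an explicit, reproducible
construction rather than a post-hoc ROC readout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.calibration import CalibratedClassifierCV
from sklearn.model_selection import GridSearchCV, RepeatedStratifiedKFold, StratifiedKFold
from sklearn.svm import SVC
from statsmodels.stats.proportion import proportion_confint

STAGE_ORDER = ("I", "II", "III", "IV", "unknown")


@dataclass
class TrainConfig:
    cv_folds: int = 5
    cv_repeats: int = 5
    kernel: str = "linear"                       # linear | rbf
    C_grid: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0)
    gamma_grid: tuple = ("scale",)
    class_weight: str | None = "balanced"
    probability: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.cv_repeats < 1:
            raise ValueError("cv_repeats must be >= 1")
        if self.kernel not in ("linear", "rbf"):
            raise ValueError(f"unknown kernel {self.kernel!r}")


@dataclass
class ScreeningModel:
    """Fitted scorer restricted to a fixed, ordered panel of features.

    ``estimator`` provides raw decision scores; ``calibrated`` (present when
    trained with ``probability=True``) is a Platt-scaled wrapper fitted by
    internal CV, for stages that must multiply probabilities.
    """

    estimator: object
    features: list[str]
    positive_class: object
    cv_best_auc: float
    cv_best_params: dict
    calibrated: object | None = None

    def _restrict(self, X: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.features if f not in X.columns]
        if missing:
            raise ValueError(f"missing panel feature columns: {missing[:5]}")
        return X[self.features].to_numpy()

    def scores(self, X: pd.DataFrame) -> pd.Series:
        return pd.Series(self.estimator.decision_function(self._restrict(X)),
                         index=X.index, name="score")

    def probabilities(self, X: pd.DataFrame) -> pd.Series:
        if self.calibrated is None:
            raise ValueError("model was trained without probability calibration")
        proba = self.calibrated.predict_proba(self._restrict(X))
        pos = list(self.calibrated.classes_).index(1)
        return pd.Series(proba[:, pos], index=X.index, name="probability")


@dataclass
class CalibratedClassifier:
    """A ScreeningModel plus a threshold tied to a target specificity."""

    model: ScreeningModel
    threshold: float
    target_specificity: float
    achieved_specificity: float
    n_calibration_controls: int

    def scores(self, X: pd.DataFrame) -> pd.Series:
        return self.model.scores(X)

    def predict(self, X: pd.DataFrame) -> pd.Series:
        return (self.scores(X) >= self.threshold).rename("positive")


def train_screening_model(
    X: pd.DataFrame, y: pd.Series | np.ndarray, config: TrainConfig
) -> ScreeningModel:
    """Tune and fit the balanced SVM on panel-restricted discovery data.

    ``y`` is binary; its larger label (sorted order) is treated as the
    positive (cancer) class and mapped to 1 internally so decision scores
    increase with cancer likelihood.
    """
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {list(classes)}")
    positive = classes[1]
    ybin = (y == positive).astype(int)
    counts = np.bincount(ybin)
    if counts.min() < config.cv_folds:
        raise ValueError(
            f"smallest class has {counts.min()} samples; fewer than cv_folds={config.cv_folds}"
        )
    grid = {"C": list(config.C_grid)}
    if config.kernel == "rbf":
        grid["gamma"] = list(config.gamma_grid)
    cv = RepeatedStratifiedKFold(n_splits=config.cv_folds, n_repeats=config.cv_repeats,
                                 random_state=config.seed)
    base = SVC(kernel=config.kernel, class_weight=config.class_weight,
               random_state=config.seed)
    search = GridSearchCV(base, grid, scoring="roc_auc", cv=cv, n_jobs=None, refit=True)
    search.fit(X.to_numpy(), ybin)
    calibrated = None
    if config.probability:
        inner = StratifiedKFold(n_splits=min(3, int(np.min(counts))), shuffle=True,
                                random_state=config.seed)
        calibrated = CalibratedClassifierCV(
            SVC(kernel=config.kernel, class_weight=config.class_weight,
                random_state=config.seed, **search.best_params_),
            method="sigmoid", cv=inner)
        calibrated.fit(X.to_numpy(), ybin)
    return ScreeningModel(
        estimator=search.best_estimator_,
        features=list(X.columns),
        positive_class=positive,
        cv_best_auc=float(search.best_score_),
        cv_best_params=dict(search.best_params_),
        calibrated=calibrated,
    )


def calibrate_threshold(
    control_scores: np.ndarray | pd.Series, target_specificity: float
) -> tuple[float, float]:
    """Smallest threshold with control exceedance <= 1 - target.

    Positive calls are ``score >= threshold``.  With n controls at most
    ``floor((1 - target) * n)`` of them may sit at or above the cutoff;
    ties are handled by stepping just past the offending score, so the
    achieved specificity can exceed, but never undershoot, the target on
    the calibration data.  Returns (threshold, achieved specificity).
    """
    s = np.sort(np.asarray(control_scores, dtype=float))
    if s.size == 0:
        raise ValueError("need at least one control score")
    if not 0 < target_specificity <= 1:
        raise ValueError("target specificity must lie in (0,1]")
    n = s.size
    k = int(np.floor((1.0 - target_specificity) * n))  # allowed exceedances
    if k == 0:
        if target_specificity < 1.0 and (1.0 - target_specificity) < 1.0 / n:
            warnings.warn(
                f"target specificity {target_specificity} is unreachable with {n} controls; "
                f"using a threshold above the maximum control score"
            )
        threshold = float(np.nextafter(s[-1], np.inf))
    else:
        threshold = float(np.nextafter(s[n - k - 1], np.inf))
    achieved = float(np.mean(s < threshold))
    return threshold, achieved


def calibrate(
    model: ScreeningModel,
    X_controls: pd.DataFrame,
    target_specificity: float,
) -> CalibratedClassifier:
    scores = model.scores(X_controls)
    threshold, achieved = calibrate_threshold(scores.to_numpy(), target_specificity)
    return CalibratedClassifier(
        model=model, threshold=threshold, target_specificity=target_specificity,
        achieved_specificity=achieved, n_calibration_controls=len(scores),
    )


def detection_rate_by_stage(
    scores: pd.Series,
    threshold: float,
    meta: pd.DataFrame,
    cancer_groups: tuple[str, ...] = ("LC", "GC", "CRC"),
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Sensitivity per tumor stage (and overall) at a fixed threshold.

    Only cancer samples enter; each cell carries an exact (Clopper-Pearson)
    binomial confidence interval.  Empty strata are reported as NaN, not 0.
    """
    meta = meta.loc[scores.index.intersection(meta.index)]
    cancer = meta.index[meta["group"].isin(cancer_groups)]
    detected = scores.loc[cancer] >= threshold
    stage = meta.loc[cancer, "stage"]
    rows = []
    strata = [(s, stage == s) for s in STAGE_ORDER] + [("overall", pd.Series(True, index=cancer))]
    for name, mask in strata:
        n = int(mask.sum())
        if n == 0:
            rows.append((name, 0, np.nan, np.nan, np.nan, np.nan))
            continue
        d = int(detected[mask].sum())
        lo, hi = proportion_confint(d, n, alpha=1 - ci_level, method="beta")
        rows.append((name, n, d, d / n, float(lo), float(hi)))
    return pd.DataFrame(
        rows, columns=["stage", "n", "detected", "rate", "ci_lower", "ci_upper"]
    ).set_index("stage")


def age_confound_check(scores: pd.Series | np.ndarray,
                       ages: pd.Series | np.ndarray) -> tuple[float, float]:
    """Pearson correlation of prediction score vs age with two-sided p-value."""
    s = np.asarray(scores, dtype=float)
    a = np.asarray(ages, dtype=float)
    if s.size != a.size:
        raise ValueError("scores and ages must be paired")
    if s.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(s) == 0 or np.ptp(a) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r, p = stats.pearsonr(s, a)
    return float(r), float(p)
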