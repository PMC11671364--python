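"""Two-stage tumor-origin prediction: LC vs non-LC, then GC vs CRC.

Panel A is selected to separate lung cancer from the two gastrointestinal
cancers; panel B separates gastric from colorectal cancer and is selected
with panel A excluded, so the panels are disjoint by construction.  Each
stage is a class-weight-balanced SVM with Platt-scaled probabilities; the
hierarchical composition yields exact three-class probabilities

    P(LC),  (1 - P(LC)) * P(GC | non-LC),  (1 - P(LC)) * P(CRC | non-LC)

which sum to 1 per sample.  An alternative "ovr-stacked" mode adds bagged
one-vs-rest scorers over the pooled panel and a logistic stacking combiner
fitted on out-of-fold base scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import BaggingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from sklearn.svm import SVC

from .panels import Panel, SelectionConfig, make_disjoint, select_per_platform_and_merge
from .screening import ScreeningModel, TrainConfig, train_screening_model

CLASS_ORDER = ("LC", "GC", "CRC")


@dataclass
class OriginModel:
    stage1: ScreeningModel              # LC vs non-LC on panel A
    stage2: ScreeningModel              # GC vs CRC on panel B
    panel_a: Panel
    panel_b: Panel
    mode: str = "hierarchical"          # hierarchical | ovr-stacked
    class_order: tuple[str, ...] = CLASS_ORDER
    ovr_models: dict = field(default_factory=dict)
    stacker: object | None = None

    def __post_init__(self):
        overlap = set(self.panel_a.feature_ids) & set(self.panel_b.feature_ids)
        if overlap:
            raise ValueError(f"panels A and B overlap: {sorted(overlap)[:5]}")

    @property
    def pooled_features(self) -> list[str]:
        return self.panel_a.feature_ids + self.panel_b.feature_ids


def _restrict(X: pd.DataFrame, features: list[str]) -> pd.DataFrame:
    missing = [f for f in features if f not in X.columns]
    if missing:
        raise ValueError(f"missing panel feature column {missing[0]!r}")
    return X[features]


def _platform_views(X: pd.DataFrame, platform_map: dict[str, str]) -> dict[str, pd.DataFrame]:
    views: dict[str, list[str]] = {}
    for col in X.columns:
        views.setdefault(platform_map.get(col, "all"), []).append(col)
    return {name: X[cols] for name, cols in views.items()}


def train_origin_model(
    X: pd.DataFrame,
    labels: pd.Series,
    selection_config: SelectionConfig,
    train_config: TrainConfig,
    platform_map: dict[str, str] | None = None,
    mode: str = "hierarchical",
) -> OriginModel:
    """Select disjoint panels and fit both stage scorers (plus OvR stack).

    ``labels`` take values LC/GC/CRC; all three must be present.  Stage
    scorers output Platt-scaled probabilities because the hierarchy
    multiplies them.
    """
    if mode not in ("hierarchical", "ovr-stacked"):
        raise ValueError(f"unknown mode {mode!r}")
    labels = pd.Series(labels, index=X.index)
    present = set(labels.unique())
    if not set(CLASS_ORDER) <= present:
        raise ValueError(f"need all of {CLASS_ORDER}, got {sorted(present)}")
    platform_map = platform_map or {c: "all" for c in X.columns}

    y_lc = (labels == "LC").astype(int)
    views = _platform_views(X, platform_map)
    panel_a = select_per_platform_and_merge(views, y_lc, selection_config, label="LC-vs-nonLC")
    if len(panel_a) == 0:
        raise ValueError("panel A came back empty; lower the frequency threshold")

    gi = labels.isin(["GC", "CRC"])
    y_gc = (labels[gi] == "GC").astype(int)
    views_gi = _platform_views(X.loc[gi.to_numpy()], platform_map)
    panel_b = select_per_platform_and_merge(
        views_gi, y_gc, selection_config, exclude=set(panel_a.feature_ids),
        label="GC-vs-CRC",
    )
    panel_b = make_disjoint(panel_b, panel_a)  # exclusion already guarantees it; assert anyway

    prob_cfg = TrainConfig(**{**train_config.__dict__, "probability": True})
    stage1 = train_screening_model(_restrict(X, panel_a.feature_ids), y_lc, prob_cfg)
    stage2 = train_screening_model(
        _restrict(X.loc[gi.to_numpy()], panel_b.feature_ids), y_gc, prob_cfg)

    model = OriginModel(stage1=stage1, stage2=stage2, panel_a=panel_a, panel_b=panel_b,
                        mode=mode)
    if mode == "ovr-stacked":
        _fit_ovr_stack(model, X, labels, train_config)
    return model


def _base_scores(model: OriginModel, X: pd.DataFrame) -> pd.DataFrame:
    p_lc = model.stage1.probabilities(_restrict(X, model.panel_a.feature_ids))
    p_gc_given = model.stage2.probabilities(_restrict(X, model.panel_b.feature_ids))
    return pd.DataFrame({"p_lc": p_lc, "p_gc_given_nonlc": p_gc_given})


def _fit_ovr_stack(model: OriginModel, X: pd.DataFrame, labels: pd.Series,
                   train_config: TrainConfig, n_bags: int = 25) -> None:
    pooled = _restrict(X, model.pooled_features)
    seed = train_config.seed
    for i, cls in enumerate(model.class_order):
        base = CalibratedClassifierCV(
            SVC(kernel=train_config.kernel, C=1.0, class_weight="balanced",
                random_state=seed + i),
            method="sigmoid", cv=3)
        bag = BaggingClassifier(base, n_estimators=n_bags, random_state=seed + i)
        bag.fit(pooled.to_numpy(), (labels == cls).astype(int).to_numpy())
        model.ovr_models[cls] = bag
    # stacking features: out-of-fold stage probabilities + in-bag OvR scores
    base_feats = _stack_features(model, X, labels, seed, out_of_fold=True,
                                 train_config=train_config)
    stacker = LogisticRegression(C=1.0, max_iter=1000, random_state=seed)
    stacker.fit(base_feats.to_numpy(), labels.to_numpy())
    model.stacker = stacker


def _stack_features(model: OriginModel, X: pd.DataFrame, labels: pd.Series | None,
                    seed: int, out_of_fold: bool,
                    train_config: TrainConfig | None = None) -> pd.DataFrame:
    pooled = _restrict(X, model.pooled_features)
    if out_of_fold and labels is not None and train_config is not None:
        cv = StratifiedKFold(n_splits=3, shuffle=True, random_state=seed)
        prob_cfg = TrainConfig(**{**train_config.__dict__, "probability": True})
        sa = _restrict(X, model.panel_a.feature_ids).to_numpy()
        est1 = CalibratedClassifierCV(
            SVC(kernel=prob_cfg.kernel, class_weight="balanced", random_state=seed),
            method="sigmoid", cv=3)
        p_lc = cross_val_predict(est1, sa, (labels == "LC").astype(int),
                                 cv=cv, method="predict_proba")[:, 1]
        # stage-2 probability is only defined on GI samples; use fitted model
        p_gc = model.stage2.probabilities(
            _restrict(X, model.panel_b.feature_ids)).to_numpy()
        cols = {"p_lc": p_lc, "p_gc_given_nonlc": p_gc}
    else:
        base = _base_scores(model, X)
        cols = {"p_lc": base["p_lc"].to_numpy(),
                "p_gc_given_nonlc": base["p_gc_given_nonlc"].to_numpy()}
    for cls in model.class_order:
        cols[f"ovr_{cls}"] = model.ovr_models[cls].predict_proba(pooled.to_numpy())[:, 1]
    return pd.DataFrame(cols, index=X.index)


def predict_origin(model: OriginModel, X: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Per-sample class probabilities (LC, GC, CRC order) and argmax labels.

    Ties break by class priority LC > GC > CRC (first maximum in class
    order).  In hierarchical mode the probabilities are the exact two-stage
    composition and sum to 1 per sample.
    """
    if model.mode == "ovr-stacked" and model.stacker is not None:
        feats = _stack_features(model, X, None, 0, out_of_fold=False)
        raw = model.stacker.predict_proba(feats.to_numpy())
        order = [list(model.stacker.classes_).index(c) for c in model.class_order]
        probs = pd.DataFrame(raw[:, order], index=X.index, columns=model.class_order)
    else:
        base = _base_scores(model, X)
        p_lc = base["p_lc"]
        p_gc = (1.0 - p_lc) * base["p_gc_given_nonlc"]
        p_crc = (1.0 - p_lc) * (1.0 - base["p_gc_given_nonlc"])
        probs = pd.DataFrame({"LC": p_lc, "GC": p_gc, "CRC": p_crc},
                             index=X.index)[list(model.class_order)]
    arg = probs.to_numpy().argmax(axis=1)  # first max -> LC > GC > CRC priority
    labels = pd.Series([model.class_order[i] for i in arg], index=X.index, name="origin")
    return probs, labels


def ovr_scores_from_probabilities(probs: pd.DataFrame) -> dict[str, pd.Series]:
    """One-vs-rest score per class, for per-class AUC evaluation."""
    return {cls: probs[cls] for cls in probs.columns}
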