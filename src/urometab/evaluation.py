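"""Model evaluation: ROC/AUC with bootstrap intervals and confusion matrices.

AUC is the Mann-Whitney concordance probability (ties counted 1/2); the
ROC convention is score >= threshold => predicted positive, thresholds
swept over the distinct scores.  Confidence intervals are stratified
percentile bootstrap by default (resampling positives and negatives
separately), with DeLong available as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve


@dataclass
class ROCResult:
    auc: float
    ci_lower: float | None
    ci_upper: float | None
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    n_pos: int
    n_neg: int
    n_boot: int | None = None
    seed: int | None = None


@dataclass
class ConfusionMatrix:
    counts: pd.DataFrame        # rows = true class, columns = predicted
    recall: pd.Series           # per-class detection rate, diagonal / row sum
    accuracy: float


def _check_binary(scores, labels):
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    uniq = np.unique(y)
    if len(uniq) != 2:
        raise ValueError(f"need exactly two classes, got {list(uniq)}")
    ybin = (y == uniq[1]).astype(int)
    return s, ybin


def roc_auc(scores, labels) -> ROCResult:
    """AUC and the full ROC curve, without a confidence interval.

    The positive class is the larger of the two label values in sorted
    order (1 for 0/1 labels, "cancer" ordering is the caller's job).
    """
    s, y = _check_binary(scores, labels)
    auc = float(roc_auc_score(y, s))
    fpr, tpr, thr = roc_curve(y, s, drop_intermediate=False)
    return ROCResult(auc=auc, ci_lower=None, ci_upper=None, fpr=fpr, tpr=tpr,
                     thresholds=thr, n_pos=int(y.sum()), n_neg=int((1 - y).sum()))


def auc_bootstrap_ci(
    scores, labels, n_boot: int = 2000, level: float = 0.95,
    seed: int = 0, method: str = "percentile",
) -> tuple[float, float]:
    """Stratified bootstrap (or DeLong) interval for the AUC."""
    s, y = _check_binary(scores, labels)
    pos = s[y == 1]
    neg = s[y == 0]
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("need at least 2 samples in each class")
    if method == "delong":
        return _delong_ci(pos, neg, level)
    if method != "percentile":
        raise ValueError(f"unknown CI method {method!r}")
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        bp = pos[rng.integers(0, len(pos), len(pos))]
        bn = neg[rng.integers(0, len(neg), len(neg))]
        ys = np.concatenate([np.ones(len(bp), dtype=int), np.zeros(len(bn), dtype=int)])
        ss = np.concatenate([bp, bn])
        if np.ptp(ss) == 0:
            aucs[b] = 0.5
        else:
            aucs[b] = roc_auc_score(ys, ss)
    alpha = 1 - level
    lo, hi = np.quantile(aucs, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def _delong_ci(pos: np.ndarray, neg: np.ndarray, level: float) -> tuple[float, float]:
    """DeLong variance via placement values."""
    m, n = len(pos), len(neg)
    all_s = np.concatenate([pos, neg])
    # placement of each positive among negatives and vice versa
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / n for p in pos])
    v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / m for q in neg])
    auc = v10.mean()
    var = v10.var(ddof=1) / m + v01.var(ddof=1) / n
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(var)
    return float(np.clip(auc - half, 0, 1)), float(np.clip(auc + half, 0, 1))


def evaluate_scores(scores, labels, n_boot: int = 2000, level: float = 0.95,
                    seed: int = 0) -> ROCResult:
    """roc_auc plus a stratified bootstrap interval in one call."""
    res = roc_auc(scores, labels)
    lo, hi = auc_bootstrap_ci(scores, labels, n_boot=n_boot, level=level, seed=seed)
    res.ci_lower, res.ci_upper = lo, hi
    res.n_boot, res.seed = n_boot, seed
    return res


def confusion(pred_labels, true_labels, class_order: list[str]) -> ConfusionMatrix:
    """Counts matrix with per-class recall (detection rate) and accuracy."""
    pred = pd.Series(list(pred_labels))
    true = pd.Series(list(true_labels))
    if len(pred) != len(true):
        raise ValueError("prediction and truth lengths differ")
    if len(pred) == 0:
        raise ValueError("empty inputs")
    known = set(class_order)
    stray = (set(pred.unique()) | set(true.unique())) - known
    if stray:
        raise ValueError(f"labels outside the class order: {sorted(stray)}")
    counts = pd.DataFrame(0, index=class_order, columns=class_order, dtype=int)
    for t, p in zip(true, pred):
        counts.loc[t, p] += 1
    support = counts.sum(axis=1)
    recall = pd.Series(
        [counts.loc[c, c] / support[c] if support[c] else np.nan for c in class_order],
        index=class_order, name="recall",
    )
    accuracy = float(np.trace(counts.to_numpy()) / counts.to_numpy().sum())
    return ConfusionMatrix(counts=counts, recall=recall, accuracy=accuracy)
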