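"""Biomarker panel selection by ensemble L1-regularized logistic regression.

Stability-selection style: the discovery data are subsampled many times,
an L1-penalized logistic model with internally cross-validated penalty is
fitted on each subsample, and a metabolite's selection frequency is the
fraction of rounds in which its coefficient is nonzero.  The panel is the
set of features at or above a frequency threshold (or the top-k when a
fixed panel size is requested).  Selection runs per platform and the
per-platform panels are merged; an exclusion set supports building a second
panel disjoint from the first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_score


@dataclass
class SelectionConfig:
    n_rounds: int = 100
    subsample_fraction: float = 0.8
    lambda_rule: str = "cv-1se"          # cv-min | cv-1se
    frequency_threshold: float = 0.8
    class_balance: str = "weighted"      # weighted | subsample
    target_size: int | None = None       # top-k mode instead of thresholding
    C_grid: tuple[float, ...] = (0.003, 0.01, 0.02, 0.0316, 0.05, 0.1, 0.316, 1.0, 10.0)
    inner_cv_folds: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.n_rounds < 1:
            raise ValueError("n_rounds must be >= 1")
        if not 0 < self.subsample_fraction < 1:
            raise ValueError("subsample_fraction must lie in (0,1)")
        if not 0 < self.frequency_threshold <= 1:
            raise ValueError("frequency_threshold must lie in (0,1]")
        if self.lambda_rule not in ("cv-min", "cv-1se"):
            raise ValueError(f"unknown lambda_rule {self.lambda_rule!r}")
        if self.class_balance not in ("weighted", "subsample"):
            raise ValueError(f"unknown class_balance {self.class_balance!r}")


@dataclass
class Panel:
    """Ordered set of selected metabolites with selection frequencies.

    ``entries`` columns: feature_id, platform, frequency, sign (sign of the
    mean nonzero coefficient; positive means higher in the positive class).
    Sorted by frequency descending, ties by mean |coefficient| then id.
    """

    entries: pd.DataFrame
    label: str = "panel"

    def __post_init__(self):
        required = {"feature_id", "platform", "frequency", "sign"}
        if not required.issubset(self.entries.columns):
            raise ValueError(f"panel entries need columns {sorted(required)}")
        if self.entries["feature_id"].duplicated().any():
            raise ValueError("duplicate feature in panel")
        if len(self.entries) and not (
            (self.entries["frequency"] > 0) & (self.entries["frequency"] <= 1)
        ).all():
            raise ValueError("panel frequencies must lie in (0,1]")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.entries["feature_id"])

    def __len__(self) -> int:
        return len(self.entries)

    def to_tsv(self, path) -> None:
        self.entries.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, label: str = "panel") -> "Panel":
        return cls(pd.read_csv(path, sep="\t"), label=label)


def _fit_l1_logistic(X: np.ndarray, y: np.ndarray, config: SelectionConfig,
                     seed: int) -> np.ndarray:
    """One round: choose C by stratified inner CV (AUC), refit, return coefs."""
    class_weight = "balanced" if config.class_balance == "weighted" else None
    cv = StratifiedKFold(n_splits=config.inner_cv_folds, shuffle=True, random_state=seed)
    means, ses = [], []
    for C in config.C_grid:
        model = LogisticRegression(l1_ratio=1.0, C=C, solver="liblinear",
                                   class_weight=class_weight, max_iter=200,
                                   random_state=seed)
        scores = cross_val_score(model, X, y, cv=cv, scoring="roc_auc")
        means.append(scores.mean())
        ses.append(scores.std(ddof=1))
    means = np.asarray(means)
    best = int(np.argmax(means))
    if config.lambda_rule == "cv-1se":
        # strongest penalty (smallest C) within one across-fold SD of the best;
        # the conservative band keeps per-round models sparse, which is what
        # makes frequency voting discriminate markers from noise
        ok = np.nonzero(means >= means[best] - ses[best])[0]
        best = int(ok[0])
    model = LogisticRegression(l1_ratio=1.0, C=config.C_grid[best], solver="liblinear",
                               class_weight=class_weight, max_iter=200, random_state=seed)
    model.fit(X, y)
    return model.coef_.ravel()


def ensemble_lasso_select(
    X: pd.DataFrame,
    y: pd.Series | np.ndarray,
    config: SelectionConfig,
    exclude: set[str] | None = None,
    platform_map: dict[str, str] | None = None,
    label: str = "panel",
) -> Panel:
    """Run the subsample/fit/vote loop on one feature table.

    ``platform_map`` tags each selected feature with its platform of origin
    (default: everything tagged "all").  Deterministic given the seed; the
    per-round subsample and model seeds are derived from it, keyed by
    round index rather than column order, so shuffling columns does not
    change frequencies.
    """
    y = np.asarray(pd.Series(y, index=X.index) if not isinstance(y, pd.Series) else y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {list(classes)}")
    exclude = set(exclude or ())
    cols = sorted(c for c in X.columns if c not in exclude)
    if not cols:
        raise ValueError("exclusion set covers every feature")
    Xs = X[cols]
    ybin = (y == classes[1]).astype(int)

    ss = np.random.SeedSequence([config.seed & 0x7FFFFFFF, 77])
    round_seeds = ss.generate_state(config.n_rounds)
    nonzero_counts = pd.Series(0, index=cols, dtype=float)
    coef_sums = pd.Series(0.0, index=cols)
    abs_coef_sums = pd.Series(0.0, index=cols)

    idx0 = np.nonzero(ybin == 0)[0]
    idx1 = np.nonzero(ybin == 1)[0]
    for r in range(config.n_rounds):
        rng = np.random.default_rng(round_seeds[r])
        take0 = rng.permutation(idx0)[: max(2, int(round(config.subsample_fraction * len(idx0))))]
        take1 = rng.permutation(idx1)[: max(2, int(round(config.subsample_fraction * len(idx1))))]
        if config.class_balance == "subsample":
            m = min(len(take0), len(take1))
            take0, take1 = take0[:m], take1[:m]
        rows = np.sort(np.concatenate([take0, take1]))
        coefs = _fit_l1_logistic(Xs.to_numpy()[rows], ybin[rows], config,
                                 int(round_seeds[r] % (2**31)))
        nz = coefs != 0
        nonzero_counts[nz] += 1
        coef_sums += coefs
        abs_coef_sums += np.abs(coefs)

    freq = nonzero_counts / config.n_rounds
    mean_abs = abs_coef_sums / config.n_rounds
    sign = np.sign(coef_sums.where(nonzero_counts > 0, 0.0)).astype(int)
    table = pd.DataFrame({
        "feature_id": cols,
        "platform": [platform_map.get(c, "all") if platform_map else "all" for c in cols],
        "frequency": freq.to_numpy(),
        "sign": sign.to_numpy(),
        "mean_abs_coef": mean_abs.to_numpy(),
    })
    table = table.sort_values(
        by=["frequency", "mean_abs_coef", "feature_id"],
        ascending=[False, False, True], kind="mergesort",
    ).reset_index(drop=True)
    if config.target_size is not None:
        chosen = table.iloc[: config.target_size]
        chosen = chosen[chosen["frequency"] > 0]
    else:
        chosen = table[table["frequency"] >= config.frequency_threshold]
    entries = chosen.drop(columns=["mean_abs_coef"]).reset_index(drop=True)
    return Panel(entries=entries, label=label)


def select_per_platform_and_merge(
    platform_matrices: dict[str, pd.DataFrame],
    y: pd.Series | np.ndarray,
    config: SelectionConfig,
    exclude: set[str] | None = None,
    label: str = "panel",
) -> Panel:
    """Independent selection per platform, then concatenation with platform tags."""
    names = sorted(platform_matrices)
    ref_index = platform_matrices[names[0]].index
    for name in names[1:]:
        if not platform_matrices[name].index.equals(ref_index):
            raise ValueError(f"sample order of platform {name!r} differs from {names[0]!r}")
    parts = []
    for name in names:
        Xp = platform_matrices[name]
        excl_here = set(exclude or ()) & set(Xp.columns)
        if excl_here == set(Xp.columns):
            continue
        sub = ensemble_lasso_select(
            Xp, y, config, exclude=excl_here,
            platform_map={c: name for c in Xp.columns}, label=f"{label}:{name}",
        )
        parts.append(sub.entries)
    entries = pd.concat(parts, ignore_index=True) if parts else pd.DataFrame(
        columns=["feature_id", "platform", "frequency", "sign"])
    entries = entries.sort_values(
        by=["frequency", "feature_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return Panel(entries=entries, label=label)


def make_disjoint(panel_b_candidate: Panel, panel_a: Panel) -> Panel:
    """Remove panel A's features from a candidate panel B."""
    keep = ~panel_b_candidate.entries["feature_id"].isin(set(panel_a.feature_ids))
    entries = panel_b_candidate.entries[keep].reset_index(drop=True)
    if entries.empty:
        raise ValueError(
            "candidate panel is entirely contained in the exclusion panel; "
            "lower the frequency threshold or revisit the selection settings"
        )
    return Panel(entries=entries, label=panel_b_candidate.label)
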