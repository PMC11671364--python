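"""Feature-table preprocessing for urinary metabolomics.

Pipeline order is fixed: detection filter -> batchwise conditional
imputation -> MSTUS normalization -> QC-anchored batch correction ->
log transform and scaling.  Each stage is usable on its own; ``preprocess``
chains them and records what happened in a ``PreprocessReport``.

MSTUS ("MS total useful signal") divides each sample by the summed
intensity of the features observed in every subject sample, which cancels
the per-sample urine dilution factor exactly because dilution scales a
whole sample multiplicatively.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer

from .cohort import FeatureMatrix


@dataclass
class PreprocessConfig:
    min_detection_fraction: float = 0.80
    impute_missing_rate_threshold: float = 0.30
    impute_intensity_quantile_threshold: float = 0.25
    imputer_rounds: int = 5
    imputer_max_predictors: int = 20
    scaling_mode: str = "unit-variance"   # unit-variance | pareto | none
    log_base: float = 2.0
    batch_correction_mode: str = "qc-median"  # qc-median | none
    seed: int = 0

    def __post_init__(self):
        for x, name in ((self.min_detection_fraction, "min_detection_fraction"),
                        (self.impute_missing_rate_threshold, "impute_missing_rate_threshold"),
                        (self.impute_intensity_quantile_threshold,
                         "impute_intensity_quantile_threshold")):
            if not 0 < x < 1:
                raise ValueError(f"{name} must lie in (0,1)")
        if self.log_base <= 1:
            raise ValueError("log_base must exceed 1")
        if self.scaling_mode not in ("unit-variance", "pareto", "none"):
            raise ValueError(f"unknown scaling_mode {self.scaling_mode!r}")
        if self.batch_correction_mode not in ("qc-median", "none"):
            raise ValueError(f"unknown batch_correction_mode {self.batch_correction_mode!r}")


@dataclass
class PreprocessReport:
    """Stage-by-stage accounting for one platform."""

    platform: str = ""
    dropped_features: list[str] = field(default_factory=list)
    imputation_routes: pd.DataFrame | None = None   # batch, subset, feature_id, route
    mstus_denominators: pd.Series | None = None
    mstus_useful_features: list[str] = field(default_factory=list)
    qc_correction_log2: pd.DataFrame | None = None  # batch x feature shifts
    qc_rsd_before: pd.Series | None = None
    qc_rsd_after: pd.Series | None = None
    warnings: list[str] = field(default_factory=list)
    scaling_center: pd.Series | None = None
    scaling_scale: pd.Series | None = None

    def to_dict(self) -> dict:
        return {
            "platform": self.platform,
            "n_dropped": len(self.dropped_features),
            "dropped_features": self.dropped_features,
            "imputation_route_counts": (
                {} if self.imputation_routes is None
                else self.imputation_routes["route"].value_counts().to_dict()
            ),
            "mstus_useful_features": self.mstus_useful_features,
            "median_qc_rsd_before": (
                None if self.qc_rsd_before is None else float(self.qc_rsd_before.median())
            ),
            "median_qc_rsd_after": (
                None if self.qc_rsd_after is None else float(self.qc_rsd_after.median())
            ),
            "warnings": self.warnings,
        }


def filter_features(
    fm: FeatureMatrix, min_detection_fraction: float = 0.80
) -> tuple[FeatureMatrix, list[str]]:
    """Drop features detected in less than the given fraction of subject samples.

    Detection is computed over subject (non-QC) rows only; a feature at
    exactly the threshold is kept, strictly below is discarded.
    """
    subj = fm.subject_values()
    if subj.empty:
        raise ValueError("no subject samples to compute detection over")
    detection = subj.notna().mean(axis=0)
    keep = detection >= min_detection_fraction
    dropped = [f for f in fm.feature_ids if not keep[f]]
    if not keep.any():
        raise ValueError(
            f"all {len(dropped)} features fall below detection fraction "
            f"{min_detection_fraction} on platform {fm.platform}"
        )
    return fm.copy_with(fm.values.loc[:, keep[keep].index]), dropped


def _impute_block(
    block: pd.DataFrame,
    global_half_min: pd.Series,
    config: PreprocessConfig,
    rng_seed: int,
    report_rows: list,
    batch: str,
    subset: str,
    warn_sink: list[str],
) -> pd.DataFrame:
    """Impute one (batch, subject-or-QC) block in place and log the routes."""
    out = block.copy()
    miss_rate = out.isna().mean(axis=0)
    mean_obs = out.mean(axis=0)
    # intensity threshold: quantile of per-feature mean observed intensity in this block
    finite_means = mean_obs.dropna()
    intensity_cut = (
        finite_means.quantile(config.impute_intensity_quantile_threshold)
        if not finite_means.empty else np.inf
    )

    routes = {}
    for f in out.columns:
        if miss_rate[f] == 0.0:
            routes[f] = "none"
        elif miss_rate[f] == 1.0:
            routes[f] = "half-minimum-global"
        elif (miss_rate[f] <= config.impute_missing_rate_threshold
              and mean_obs[f] > intensity_cut):
            routes[f] = "iterative"
        else:
            routes[f] = "half-minimum"

    for f, route in routes.items():
        if route == "half-minimum":
            out[f] = out[f].fillna(out[f].min() / 2.0)
        elif route == "half-minimum-global":
            out[f] = out[f].fillna(global_half_min[f])
            warn_sink.append(
                f"feature {f} entirely missing in batch {batch} ({subset}); "
                f"imputed with half the global minimum"
            )

    iter_feats = [f for f, r in routes.items() if r == "iterative"]
    if iter_feats:
        # chained-model imputation on log scale over the full block, using the
        # already-complete columns as predictors
        logged = np.log2(out)
        imputer = IterativeImputer(
            max_iter=config.imputer_rounds, random_state=rng_seed % (2**31),
            sample_posterior=False, keep_empty_features=True,
            n_nearest_features=min(config.imputer_max_predictors, logged.shape[1] - 1),
        )
        filled = pd.DataFrame(
            imputer.fit_transform(logged.to_numpy()), index=out.index, columns=out.columns
        )
        for f in iter_feats:
            col = np.exp2(filled[f])
            out[f] = out[f].where(out[f].notna(), col)

    for f in out.columns:
        report_rows.append((batch, subset, f, routes[f]))
    return out


def impute(
    fm: FeatureMatrix, config: PreprocessConfig
) -> tuple[FeatureMatrix, pd.DataFrame]:
    """Batchwise conditional imputation; subject and QC rows handled separately.

    Features with low missing rate and high mean intensity within the batch
    are imputed by iterative chained-model multivariate imputation; every
    other feature with missing cells gets half its minimum observed value in
    the batch.  Observed cells are never altered.
    """
    values = fm.values
    global_half_min = values.min(axis=0) / 2.0
    if global_half_min.isna().any():
        # feature never observed anywhere: nothing sane to impute from
        bad = list(global_half_min.index[global_half_min.isna()])
        raise ValueError(f"features never observed in any sample: {bad}")

    report_rows: list = []
    warn_sink: list[str] = []
    pieces = []
    for b, batch_idx in values.groupby(fm.batch, sort=True).groups.items():
        for subset, flag in (("subject", False), ("qc", True)):
            rows = [s for s in batch_idx if bool(fm.is_qc[s]) == flag]
            if not rows:
                continue
            tag = zlib.crc32(f"{b}:{subset}".encode())
            seed = (config.seed * 1000003 + tag) % (2**31)
            block = _impute_block(values.loc[rows], global_half_min, config, seed,
                                  report_rows, str(b), subset, warn_sink)
            pieces.append(block)
    out = pd.concat(pieces).loc[values.index]
    for msg in warn_sink:
        warnings.warn(msg)
    routes = pd.DataFrame(report_rows, columns=["batch", "subset", "feature_id", "route"])
    routes.attrs["warnings"] = warn_sink
    return fm.copy_with(out), routes


def mstus_useful_features(fm: FeatureMatrix) -> list[str]:
    """Features observed (pre-imputation) in 100% of subject samples."""
    subj = fm.subject_values()
    full = subj.notna().all(axis=0)
    useful = list(full[full].index)
    return useful if useful else list(fm.feature_ids)


def mstus_normalize(
    fm: FeatureMatrix, useful_features: list[str] | None = None
) -> tuple[FeatureMatrix, pd.Series]:
    """Divide each sample by its total signal over the useful feature set."""
    if useful_features is None:
        useful_features = mstus_useful_features(fm)
    missing = set(useful_features) - set(fm.feature_ids)
    if missing:
        raise ValueError(f"useful features not in matrix: {sorted(missing)[:5]}")
    denom = fm.values[useful_features].sum(axis=1, skipna=True)
    if (denom <= 0).any() or denom.isna().any():
        bad = denom.index[(denom <= 0) | denom.isna()][0]
        raise ValueError(f"nonpositive MSTUS denominator for sample {bad!r}")
    out = fm.values.div(denom, axis=0)
    denom.name = "mstus_denominator"
    return fm.copy_with(out), denom


def qc_batch_correct(
    fm: FeatureMatrix, mode: str = "qc-median", log_base: float = 2.0
) -> tuple[FeatureMatrix, pd.DataFrame | None]:
    """Align each batch's QC median to the grand QC median, per feature, in log space.

    Subject and QC rows in a batch receive the same correction, so a batch
    shift shared by both (the instrument-drift model the QC design assumes)
    is removed.
    """
    if mode == "none":
        return fm, None
    if mode != "qc-median":
        raise ValueError(f"unknown batch correction mode {mode!r}")
    if fm.values.isna().any().any():
        raise ValueError("batch correction requires a complete (imputed) matrix")
    qc_rows = fm.values.loc[fm.is_qc.to_numpy()]
    if qc_rows.empty:
        raise ValueError("qc-median correction requires QC samples")
    log = np.log(fm.values) / np.log(log_base)
    log_qc = np.log(qc_rows) / np.log(log_base)
    grand = log_qc.median(axis=0)
    qc_batches = fm.batch.loc[qc_rows.index]
    shifts = {}
    for b in pd.unique(fm.batch):
        rows = log_qc.loc[qc_batches.index[qc_batches == b]]
        if rows.empty:
            raise ValueError(f"batch {b!r} has no QC samples; cannot qc-median correct")
        shifts[b] = rows.median(axis=0) - grand
    shift_df = pd.DataFrame(shifts).T.loc[pd.unique(fm.batch)]
    corrected = log.sub(shift_df.loc[fm.batch.to_numpy()].set_axis(log.index), axis=0)
    out = np.power(log_base, corrected)
    return fm.copy_with(out), shift_df


def qc_rsd(fm: FeatureMatrix) -> pd.Series:
    """Per-feature relative SD (SD/mean) across pooled QC injections."""
    qc = fm.values.loc[fm.is_qc.to_numpy()]
    if qc.empty:
        raise ValueError("no QC samples")
    return qc.std(axis=0, ddof=1) / qc.mean(axis=0)


def log_scale(
    fm: FeatureMatrix,
    config: PreprocessConfig,
    discovery_ids: list[str] | None = None,
    center: pd.Series | None = None,
    scale: pd.Series | None = None,
) -> tuple[FeatureMatrix, pd.Series | None, pd.Series | None]:
    """Log transform then per-feature center/scale.

    Scaling parameters are fitted on the discovery subject samples only
    (or taken from ``center``/``scale`` if supplied) and applied to every
    row, so validation data are transformed without leakage.
    """
    vals = fm.values
    if (vals <= 0).any().any():
        col = vals.columns[(vals <= 0).any(axis=0)][0]
        row = vals.index[(vals[col] <= 0)][0]
        raise ValueError(f"non-positive value at sample {row!r}, feature {col!r}")
    logv = np.log(vals) / np.log(config.log_base)
    if config.scaling_mode == "none":
        return fm.copy_with(logv, require_positive=False), None, None
    if center is None or scale is None:
        if discovery_ids is None:
            fit_rows = logv.loc[~fm.is_qc.to_numpy()]
        else:
            fit_rows = logv.loc[[s for s in discovery_ids if s in logv.index]]
        if fit_rows.empty:
            raise ValueError("no rows available to fit scaling parameters")
        center = fit_rows.mean(axis=0)
        sd = fit_rows.std(axis=0, ddof=0)
        sd = sd.where(sd > 0, 1.0)  # constant feature: center only
        scale = sd if config.scaling_mode == "unit-variance" else np.sqrt(sd)
    out = logv.sub(center, axis=1).div(scale, axis=1)
    return fm.copy_with(out, require_positive=False), center, scale


def preprocess(
    fm: FeatureMatrix,
    config: PreprocessConfig,
    discovery_ids: list[str] | None = None,
) -> tuple[FeatureMatrix, PreprocessReport]:
    """Run the full fixed-order pipeline on one platform."""
    report = PreprocessReport(platform=fm.platform)
    fm1, dropped = filter_features(fm, config.min_detection_fraction)
    report.dropped_features = dropped
    report.mstus_useful_features = mstus_useful_features(fm1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fm2, routes = impute(fm1, config)
    report.imputation_routes = routes
    report.warnings.extend(routes.attrs.get("warnings", []))
    fm3, denom = mstus_normalize(fm2, report.mstus_useful_features)
    report.mstus_denominators = denom
    if config.batch_correction_mode == "qc-median" and fm3.is_qc.any():
        report.qc_rsd_before = qc_rsd(fm3)
        fm4, shifts = qc_batch_correct(fm3, config.batch_correction_mode, config.log_base)
        report.qc_correction_log2 = shifts
        report.qc_rsd_after = qc_rsd(fm4)
    else:
        fm4 = fm3
    fm5, center, scale = log_scale(fm4, config, discovery_ids)
    report.scaling_center, report.scaling_scale = center, scale
    return fm5, report


def preprocess_cohort(
    matrices: dict[str, FeatureMatrix],
    meta: pd.DataFrame,
    config: PreprocessConfig,
) -> tuple[pd.DataFrame, dict[str, PreprocessReport]]:
    """Preprocess every platform and concatenate subject rows feature-wise.

    Returns a single samples x features table (subject samples only, platform
    feature IDs are globally unique) plus the per-platform reports.  Scaling
    is fitted on the discovery cohort listed in ``meta['cohort']``.
    """
    discovery_ids = list(meta.index[meta["cohort"] == "discovery"])
    blocks = []
    reports = {}
    for platform in sorted(matrices):
        proc, rep = preprocess(matrices[platform], config, discovery_ids)
        reports[platform] = rep
        blocks.append(proc.values.loc[~proc.is_qc.to_numpy()])
    X = pd.concat(blocks, axis=1)
    X = X.loc[[s for s in meta.index if s in X.index]]
    return X, reports
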