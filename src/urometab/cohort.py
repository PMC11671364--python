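"""Synthetic multi-platform urinary-metabolomics cohorts.

Generates case-control cohorts with the statistical structure a urine
metabolomics screening study has to cope with: three MS platforms measured
separately (polar, lipid, GC), five clinical groups (three cancers, benign
disease controls, healthy controls), per-sample urine dilution, per-batch
instrument effects anchored by pooled QC injections, log-normal measurement
noise, and intensity-dependent (censoring) plus completely-random
missingness.  Group differences are planted explicitly as ``EffectSpec``
entries, and every corruption applied is recorded in a ``TruthRecord`` so
downstream stages can be tested against ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

GROUPS = ("LC", "GC", "CRC", "NCD", "HC")
CANCER_GROUPS = ("LC", "GC", "CRC")
CONTROL_GROUPS = ("NCD", "HC")
STAGES = ("I", "II", "III", "IV", "unknown")

#: Feature counts per platform matching a three-platform urinary assay
#: (polar metabolites by LC-MS, lipids, and GC-MS volatiles/derivatives).
DEFAULT_PLATFORM_SIZES = {"polar": 125, "lipid": 13, "gc": 222}

#: Stage mix of the cancer arm (stage at diagnosis; "unknown" covers
#: non-metastatic cases without staging information).
DEFAULT_STAGE_FRACTIONS = {"I": 0.30, "II": 0.11, "III": 0.17, "IV": 0.15, "unknown": 0.27}

#: Default stage modulation of planted effects: muted at stage I, full at
#: II/III, partially reverted at IV (late-stage metabolic drift), mixed for
#: unstaged cases.
DEFAULT_STAGE_MULTIPLIERS = {"I": 0.3, "II": 1.0, "III": 1.0, "IV": 0.6, "unknown": 0.8}

#: Discovery/validation group sizes of a ~1700-participant three-center study.
DEFAULT_N_PER_GROUP = {"LC": 548, "GC": 177, "CRC": 186, "NCD": 563, "HC": 229}

#: Named contrasts resolved to the set of shifted groups.
NAMED_CONTRASTS = {
    "cancer": CANCER_GROUPS,
    "LC": ("LC",),
    "GC": ("GC",),
    "CRC": ("CRC",),
    "non-LC": ("GC", "CRC"),
}


def platform_feature_ids(platform_sizes: dict[str, int] | None = None) -> dict[str, list[str]]:
    """Deterministic feature identifiers, globally unique across platforms."""
    sizes = dict(DEFAULT_PLATFORM_SIZES if platform_sizes is None else platform_sizes)
    out = {}
    for name, n in sizes.items():
        width = max(3, len(str(n)))
        out[name] = [f"{name}_{i:0{width}d}" for i in range(1, n + 1)]
    return out


@dataclass(frozen=True)
class EffectSpec:
    """A planted group difference on one metabolite.

    The shift is additive on the log2 scale: samples whose group is in
    ``contrast`` receive ``direction * base_log2_effect *
    stage_multipliers[stage]`` (multiplier 1 for unstaged control groups
    that are part of the contrast).
    """

    feature_id: str
    contrast: tuple[str, ...] | str = "cancer"
    base_log2_effect: float = 1.0
    stage_multipliers: dict[str, float] | None = None
    direction: int = 1

    def shifted_groups(self) -> tuple[str, ...]:
        if isinstance(self.contrast, str):
            try:
                return NAMED_CONTRASTS[self.contrast]
            except KeyError:
                raise ValueError(f"unknown named contrast {self.contrast!r}") from None
        unknown = set(self.contrast) - set(GROUPS)
        if unknown:
            raise ValueError(f"contrast references unknown groups {sorted(unknown)}")
        return tuple(self.contrast)

    def multiplier(self, stage: str) -> float:
        mults = self.stage_multipliers or DEFAULT_STAGE_MULTIPLIERS
        if stage == "not-applicable":
            return 1.0
        if stage not in mults:
            raise ValueError(f"stage {stage!r} has no multiplier in {self.feature_id} effect")
        return mults[stage]


@dataclass(frozen=True)
class MissingnessSpec:
    """Censoring-at-low-intensity (MNAR) plus completely-random (MCAR) dropout.

    Below the ``mnar_intensity_quantile`` of the platform's log-intensity
    distribution the censoring probability ramps linearly from 0 up to
    ``mnar_max_prob`` at the platform minimum.
    """

    mnar_intensity_quantile: float = 0.15
    mnar_max_prob: float = 0.35
    mcar_prob: float = 0.02

    def __post_init__(self):
        if not 0 < self.mnar_intensity_quantile < 1:
            raise ValueError("mnar_intensity_quantile must lie in (0,1)")
        for p, name in ((self.mnar_max_prob, "mnar_max_prob"), (self.mcar_prob, "mcar_prob")):
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must lie in [0,1]")


@dataclass
class CohortConfig:
    """Study design and corruption parameters for one synthetic cohort."""

    n_per_group: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_N_PER_GROUP))
    stage_fractions: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_STAGE_FRACTIONS))
    platform_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_PLATFORM_SIZES))
    n_batches: int = 4
    qc_per_batch: int = 3
    dilution_log_sd: float = 0.5    # natural-log SD of the per-sample dilution factor
    batch_log_sd: float = 0.3      # natural-log SD of per-(feature, batch) shifts
    noise_log_sd: float = 0.2      # natural-log SD of per-cell measurement noise
    baseline_log2_mean_range: tuple[float, float] = (10.0, 20.0)
    baseline_log2_sd: float = 0.6  # biological between-subject spread per feature
    planted: list[EffectSpec] = field(default_factory=list)
    missingness: MissingnessSpec = field(default_factory=MissingnessSpec)
    discovery_fraction: float = 0.77
    seed: int = 0

    def __post_init__(self):
        unknown = set(self.n_per_group) - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown groups {sorted(unknown)}")
        if any(n < 0 for n in self.n_per_group.values()):
            raise ValueError("group sizes must be >= 0")
        if set(self.stage_fractions) != set(STAGES):
            raise ValueError(f"stage_fractions must cover exactly {STAGES}")
        if abs(sum(self.stage_fractions.values()) - 1.0) > 1e-9:
            raise ValueError("stage_fractions must sum to 1")
        if len(set(self.platform_sizes)) != len(self.platform_sizes):
            raise ValueError("platform names must be unique")
        if self.n_batches < 1:
            raise ValueError("n_batches must be >= 1")
        if self.qc_per_batch < 0:
            raise ValueError("qc_per_batch must be >= 0")
        for sd, name in ((self.dilution_log_sd, "dilution_log_sd"),
                         (self.batch_log_sd, "batch_log_sd"),
                         (self.noise_log_sd, "noise_log_sd")):
            if sd < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not 0 < self.discovery_fraction < 1:
            raise ValueError("discovery_fraction must lie in (0,1)")

    def feature_ids(self) -> dict[str, list[str]]:
        return platform_feature_ids(self.platform_sizes)


@dataclass
class FeatureMatrix:
    """One platform's samples x metabolites intensity table.

    ``values`` holds strictly positive intensities with NaN marking missing
    cells; ``batch`` and ``is_qc`` annotate every row (subject and QC).
    """

    platform: str
    values: pd.DataFrame
    batch: pd.Series
    is_qc: pd.Series
    #: raw intensity tables must be strictly positive; log/scaled tables not
    require_positive: bool = True

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            dup = v.index[v.index.duplicated()][0]
            raise ValueError(f"duplicate sample id {dup!r} in platform {self.platform}")
        if v.columns.duplicated().any():
            dup = v.columns[v.columns.duplicated()][0]
            raise ValueError(f"duplicate feature id {dup!r} in platform {self.platform}")
        if not self.batch.index.equals(v.index) or not self.is_qc.index.equals(v.index):
            raise ValueError("batch/is_qc annotations must be indexed by sample id")
        if self.require_positive:
            arr = v.to_numpy(dtype=float)
            if np.any(arr[np.isfinite(arr)] <= 0):
                raise ValueError(f"non-positive observed intensity in platform {self.platform}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def mask(self) -> pd.DataFrame:
        """True where observed."""
        return self.values.notna()

    def subject_values(self) -> pd.DataFrame:
        return self.values.loc[~self.is_qc.to_numpy()]

    def copy_with(self, values: pd.DataFrame,
                  require_positive: bool | None = None) -> "FeatureMatrix":
        rp = self.require_positive if require_positive is None else require_positive
        return FeatureMatrix(self.platform, values, self.batch.loc[values.index],
                             self.is_qc.loc[values.index], require_positive=rp)


@dataclass
class TruthRecord:
    """Everything the corruption stages did, kept for test oracles."""

    latent: dict[str, pd.DataFrame]
    dilution: pd.Series                       # per subject sample, multiplicative
    batch_effects: dict[str, pd.DataFrame]    # platform -> (batch x feature), ln scale
    planted: list[EffectSpec]
    qc_reference: dict[str, pd.Series]        # platform -> reference profile

    def planted_feature_ids(self) -> list[str]:
        return [e.feature_id for e in self.planted]


def validate_metadata(meta: pd.DataFrame) -> None:
    """Check the clinical-metadata invariants.

    Columns: group, stage, age, sex (and optionally batch, cohort); stage is
    "not-applicable" exactly for the non-cancer groups.
    """
    required = {"group", "stage", "age", "sex"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata missing columns {sorted(missing)}")
    if meta.index.duplicated().any():
        raise ValueError("duplicate sample ids in metadata")
    bad_group = set(meta["group"]) - set(GROUPS)
    if bad_group:
        raise ValueError(f"unknown groups {sorted(bad_group)}")
    is_control = meta["group"].isin(CONTROL_GROUPS)
    na_stage = meta["stage"] == "not-applicable"
    if not (is_control == na_stage).all():
        bad = meta.index[is_control != na_stage][0]
        raise ValueError(f"stage/group mismatch for sample {bad!r}")
    bad_stage = set(meta.loc[~na_stage, "stage"]) - set(STAGES)
    if bad_stage:
        raise ValueError(f"unknown stages {sorted(bad_stage)}")


def _apportion(n: int, fractions: dict[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment so stage counts match fractions exactly."""
    keys = list(fractions)
    raw = {k: n * fractions[k] for k in keys}
    counts = {k: int(math.floor(raw[k])) for k in keys}
    short = n - sum(counts.values())
    for k in sorted(keys, key=lambda k: (-(raw[k] - counts[k]), k))[:short]:
        counts[k] += 1
    return counts


def simulate_truth(config: CohortConfig) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Latent (pre-corruption) abundances plus sample metadata.

    Baseline abundance of feature f in sample i is log-normal:
    log2 x_if = mu_f + b_if with mu_f uniform over
    ``baseline_log2_mean_range`` and b_if ~ N(0, baseline_log2_sd^2).
    Planted effects add ``direction * base_log2_effect * multiplier(stage)``
    for samples in the contrast's groups.  Deterministic given the seed.
    """
    rng = np.random.default_rng(config.seed)
    feat_ids = config.feature_ids()
    all_features = {f for ids in feat_ids.values() for f in ids}
    for eff in config.planted:
        if eff.feature_id not in all_features:
            raise ValueError(f"planted effect references unknown feature {eff.feature_id!r}")
        eff.shifted_groups()  # validate contrast

    rows = []
    for group in GROUPS:
        n = config.n_per_group.get(group, 0)
        if group in CANCER_GROUPS:
            stage_counts = _apportion(n, config.stage_fractions)
            stages = [s for s in STAGES for _ in range(stage_counts[s])]
        else:
            stages = ["not-applicable"] * n
        # age structure: cancer arm older than benign controls, HC youngest
        centre = {"LC": 62, "GC": 62, "CRC": 62, "NCD": 55, "HC": 47}[group]
        ages = np.clip(rng.normal(centre, 10, size=n).round(), 18, 93).astype(int)
        sexes = rng.choice(["F", "M"], size=n, p=[0.4, 0.6])
        for j in range(n):
            rows.append((f"{group}_{j + 1:04d}", group, stages[j], ages[j], sexes[j]))
    meta = pd.DataFrame(rows, columns=["sample_id", "group", "stage", "age", "sex"])
    meta = meta.set_index("sample_id")
    n_samples = len(meta)
    meta["batch"] = [f"B{1 + (i % config.n_batches)}" for i in rng.permutation(n_samples)]

    latent: dict[str, pd.DataFrame] = {}
    for platform, ids in feat_ids.items():
        lo, hi = config.baseline_log2_mean_range
        mu = rng.uniform(lo, hi, size=len(ids))
        log2x = mu[None, :] + rng.normal(0.0, config.baseline_log2_sd, size=(n_samples, len(ids)))
        frame = pd.DataFrame(log2x, index=meta.index, columns=ids)
        for eff in config.planted:
            if eff.feature_id not in frame.columns:
                continue
            groups = eff.shifted_groups()
            hit = meta["group"].isin(groups)
            mults = meta.loc[hit, "stage"].map(eff.multiplier).astype(float)
            frame.loc[hit, eff.feature_id] += eff.direction * eff.base_log2_effect * mults
        latent[platform] = np.exp2(frame)
    return latent, meta


def corrupt(
    latent: dict[str, pd.DataFrame],
    meta: pd.DataFrame,
    config: CohortConfig,
) -> tuple[dict[str, FeatureMatrix], TruthRecord]:
    """Apply dilution, batch effects, noise, QC injections and missingness.

    Each subject sample gets one dilution factor exp(N(0, dilution_log_sd^2))
    applied to all its features on every platform (urine concentration is a
    whole-sample property).  Batch effects are per (platform, feature, batch)
    multiplicative shifts shared by subject and QC rows.  QC rows are
    replicates of a single fixed reference profile (the geometric baseline),
    so they carry batch effect and noise but no dilution.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    for platform, frame in latent.items():
        if (frame.to_numpy() <= 0).any():
            raise ValueError(f"latent intensities must be strictly positive ({platform})")

    dilution = pd.Series(
        np.exp(rng.normal(0.0, config.dilution_log_sd, size=len(meta))), index=meta.index,
        name="dilution",
    )
    batches = [f"B{b + 1}" for b in range(config.n_batches)]
    qc_ids = [f"QC_{b}_{i + 1}" for b in batches for i in range(config.qc_per_batch)]
    qc_batch = pd.Series([b for b in batches for _ in range(config.qc_per_batch)],
                         index=qc_ids, dtype=object)

    matrices: dict[str, FeatureMatrix] = {}
    batch_effects: dict[str, pd.DataFrame] = {}
    qc_reference: dict[str, pd.Series] = {}
    for platform, frame in latent.items():
        feats = frame.columns
        be = pd.DataFrame(
            rng.normal(0.0, config.batch_log_sd, size=(len(batches), len(feats))),
            index=batches, columns=feats,
        )
        batch_effects[platform] = be
        # fixed pooled-QC reference profile: geometric mean of the latent cohort
        ref = np.exp2(np.log2(frame).mean(axis=0))
        qc_reference[platform] = ref

        subj = frame.to_numpy(dtype=float)
        subj = subj * dilution.to_numpy()[:, None]
        subj = subj * np.exp(be.loc[meta["batch"].to_numpy(), :].to_numpy())
        subj = subj * np.exp(rng.normal(0.0, config.noise_log_sd, size=subj.shape))

        qc = np.tile(ref.to_numpy()[None, :], (len(qc_ids), 1))
        if qc_ids:
            qc = qc * np.exp(be.loc[qc_batch.to_numpy(), :].to_numpy())
            qc = qc * np.exp(rng.normal(0.0, config.noise_log_sd, size=qc.shape))

        values = pd.DataFrame(
            np.vstack([subj, qc]) if qc_ids else subj,
            index=pd.Index(list(meta.index) + qc_ids, name="sample_id"), columns=feats,
        )
        # censoring: ramp to mnar_max_prob below the low-intensity quantile
        ms = config.missingness
        logv = np.log(values.to_numpy())
        q = np.quantile(logv, ms.mnar_intensity_quantile)
        lo = logv.min()
        if q > lo:
            p_mnar = ms.mnar_max_prob * np.clip((q - logv) / (q - lo), 0.0, 1.0)
        else:
            p_mnar = np.zeros_like(logv)
        p_drop = 1.0 - (1.0 - p_mnar) * (1.0 - ms.mcar_prob)
        drop = rng.random(size=logv.shape) < p_drop
        out = values.mask(drop)

        batch_col = pd.concat([meta["batch"], qc_batch]) if qc_ids else meta["batch"].copy()
        batch_col.name = "batch"
        is_qc = pd.Series([False] * len(meta) + [True] * len(qc_ids),
                          index=out.index, name="is_qc")
        matrices[platform] = FeatureMatrix(platform, out, batch_col, is_qc)

    truth = TruthRecord(latent=latent, dilution=dilution, batch_effects=batch_effects,
                        planted=list(config.planted), qc_reference=qc_reference)
    return matrices, truth


def assign_cohorts(meta: pd.DataFrame, discovery_fraction: float, seed: int) -> pd.Series:
    """Stratified-by-group random discovery/validation assignment."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    cohort = pd.Series("validation", index=meta.index, name="cohort", dtype=object)
    for group, idx in meta.groupby("group", sort=True).groups.items():
        idx = list(idx)
        n_disc = int(round(discovery_fraction * len(idx)))
        picked = rng.permutation(len(idx))[:n_disc]
        cohort.loc[[idx[i] for i in picked]] = "discovery"
    return cohort


def generate_cohort(
    config: CohortConfig,
) -> tuple[dict[str, FeatureMatrix], pd.DataFrame, TruthRecord]:
    """simulate_truth -> corrupt -> stratified cohort split, all from one seed."""
    latent, meta = simulate_truth(config)
    matrices, truth = corrupt(latent, meta, config)
    meta = meta.copy()
    meta["cohort"] = assign_cohorts(meta, config.discovery_fraction, config.seed)
    return matrices, meta, truth
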