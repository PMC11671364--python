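"""End-to-end driver: simulate -> preprocess -> select -> train -> evaluate.

``run_pipeline`` chains every stage on the discovery cohort, evaluates on
the held-out validation cohort, and writes a machine-readable metrics
summary plus the intermediate artifacts.  All randomness derives from one
global seed through a stable per-module scheme, so identical config+seed
reproduces a byte-identical summary.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as uio
from .cohort import (CANCER_GROUPS, CohortConfig, EffectSpec, MissingnessSpec,
                     generate_cohort)
from .enrichment import bundled_pathway_map, enrich
from .evaluation import confusion, evaluate_scores
from .origin import predict_origin, train_origin_model
from .panels import Panel, SelectionConfig, select_per_platform_and_merge
from .preprocess import PreprocessConfig, preprocess_cohort
from .screening import (TrainConfig, age_confound_check, calibrate,
                        detection_rate_by_stage, train_screening_model)


def derive_seed(global_seed: int, name: str) -> int:
    """Stable per-module seed below 2^31, keyed by module name."""
    return int((int(global_seed) * 2654435761 + zlib.crc32(name.encode())) % (2**31))


def default_planted_effects() -> list[EffectSpec]:
    """Demo truth: pan-cancer, LC-specific and GC-vs-CRC marker sets.

    Pan-cancer markers live in pathways of the bundled synthetic map so the
    enrichment stage has signal to find; effect sizes are strong enough for
    a small demo cohort to separate.
    """
    effects = []
    for fid in ("polar_001", "polar_002", "polar_003", "gc_001", "gc_002"):
        effects.append(EffectSpec(fid, "cancer", base_log2_effect=1.2))
    for fid, direction in (("polar_010", 1), ("polar_011", -1), ("gc_010", 1),
                           ("gc_011", 1), ("lipid_001", -1)):
        effects.append(EffectSpec(fid, "LC", base_log2_effect=2.0,
                                  stage_multipliers={s: 1.0 for s in
                                                     ("I", "II", "III", "IV", "unknown")},
                                  direction=direction))
    for fid, direction in (("polar_020", 1), ("gc_020", 1), ("gc_021", -1),
                           ("gc_022", 1)):
        effects.append(EffectSpec(fid, "GC", base_log2_effect=2.0,
                                  stage_multipliers={s: 1.0 for s in
                                                     ("I", "II", "III", "IV", "unknown")},
                                  direction=direction))
    return effects


def demo_cohort_config(seed: int = 0) -> CohortConfig:
    """Small, strongly-separated cohort for smoke runs and the demo."""
    return CohortConfig(
        n_per_group={"LC": 80, "GC": 50, "CRC": 50, "NCD": 60, "HC": 60},
        planted=default_planted_effects(),
        seed=seed,
    )


@dataclass
class RunConfig:
    cohort: CohortConfig = field(default_factory=demo_cohort_config)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    selection: SelectionConfig = field(default_factory=lambda: SelectionConfig(n_rounds=25))
    training: TrainConfig = field(default_factory=TrainConfig)
    target_specificities: tuple[float, ...] = (0.95, 0.99)
    origin_mode: str = "hierarchical"
    n_boot: int = 500
    seed: int = 0

    def __post_init__(self):
        if not self.target_specificities:
            raise ValueError("need at least one target specificity")

    def reseeded(self) -> "RunConfig":
        """Push module seeds derived from the global seed into the sub-configs."""
        import dataclasses
        return dataclasses.replace(
            self,
            cohort=dataclasses.replace(self.cohort, seed=derive_seed(self.seed, "cohort")),
            preprocess=dataclasses.replace(self.preprocess,
                                           seed=derive_seed(self.seed, "preprocess")),
            selection=dataclasses.replace(self.selection,
                                          seed=derive_seed(self.seed, "selection")),
            training=dataclasses.replace(self.training,
                                         seed=derive_seed(self.seed, "training")),
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        if "cohort" in raw:
            c = dict(raw["cohort"])
            if "planted" in c:
                c["planted"] = [EffectSpec(**{**e, "contrast": tuple(e["contrast"])
                                              if isinstance(e.get("contrast"), list)
                                              else e.get("contrast", "cancer")})
                                for e in c["planted"]]
            if "missingness" in c:
                c["missingness"] = MissingnessSpec(**c["missingness"])
            if "stage_fractions" not in c and raw.get("use_demo_effects"):
                pass
            kwargs["cohort"] = CohortConfig(**c)
        for key, cls_ in (("preprocess", PreprocessConfig), ("selection", SelectionConfig),
                          ("training", TrainConfig)):
            if key in raw:
                kwargs[key] = cls_(**raw[key])
        for key in ("target_specificities", "origin_mode", "n_boot", "seed"):
            if key in raw:
                val = raw[key]
                kwargs[key] = tuple(val) if key == "target_specificities" else val
        return cls(**kwargs)


def platform_map_from_columns(columns) -> dict[str, str]:
    return {c: c.split("_")[0] for c in columns}


def run_pipeline(config: RunConfig, outdir=None) -> dict:
    """Execute the full chain; returns (and optionally writes) the metrics."""
    cfg = config.reseeded()
    metrics: dict = {"seed": int(config.seed)}

    # -- cohort -----------------------------------------------------------
    matrices, meta, truth = generate_cohort(cfg.cohort)
    disc = meta.index[meta["cohort"] == "discovery"]
    val = meta.index[meta["cohort"] == "validation"]
    metrics["cohort"] = {
        "n_samples": int(len(meta)),
        "n_discovery": int(len(disc)),
        "n_validation": int(len(val)),
        "groups": meta["group"].value_counts().sort_index().to_dict(),
    }

    # -- preprocess -------------------------------------------------------
    X, reports = preprocess_cohort(matrices, meta, cfg.preprocess)
    metrics["preprocess"] = {p: r.to_dict() for p, r in reports.items()}
    for p in metrics["preprocess"]:
        metrics["preprocess"][p].pop("dropped_features", None)
        metrics["preprocess"][p].pop("mstus_useful_features", None)
    pmap = platform_map_from_columns(X.columns)
    X_disc, X_val = X.loc[disc], X.loc[val]
    meta_disc, meta_val = meta.loc[disc], meta.loc[val]

    # -- screening panel + model (cancer vs non-cancer) -------------------
    y_disc = meta_disc["group"].isin(CANCER_GROUPS).astype(int)
    y_val = meta_val["group"].isin(CANCER_GROUPS).astype(int)
    views = {name: X_disc[[c for c in X_disc.columns if pmap[c] == name]]
             for name in sorted(set(pmap.values()))}
    panel = select_per_platform_and_merge(views, y_disc, cfg.selection, label="screening")
    if len(panel) == 0:
        raise RuntimeError("screening panel is empty; selection found no stable features")
    metrics["screening_panel"] = {
        "size": len(panel),
        "features": panel.feature_ids,
    }

    model = train_screening_model(X_disc[panel.feature_ids], y_disc, cfg.training)
    scores_val = model.scores(X_val)
    eval_seed = derive_seed(cfg.seed, "evaluation")

    hc_mask = meta_val["group"] == "HC"
    cancer_mask = y_val == 1
    res_hc = evaluate_scores(
        scores_val[cancer_mask | hc_mask],
        y_val[cancer_mask | hc_mask], n_boot=cfg.n_boot, seed=eval_seed)
    res_all = evaluate_scores(scores_val, y_val, n_boot=cfg.n_boot, seed=eval_seed)
    metrics["screening"] = {
        "cv_auc": model.cv_best_auc,
        "auc_validation_cancer_vs_hc": {
            "auc": res_hc.auc, "ci": [res_hc.ci_lower, res_hc.ci_upper]},
        "auc_validation_cancer_vs_noncancer": {
            "auc": res_all.auc, "ci": [res_all.ci_lower, res_all.ci_upper]},
    }

    # -- calibration + stage-stratified detection -------------------------
    controls_disc = X_disc.loc[~y_disc.astype(bool)]
    metrics["detection_by_stage"] = {}
    for target in cfg.target_specificities:
        cal = calibrate(model, controls_disc, target)
        table = detection_rate_by_stage(scores_val, cal.threshold, meta_val)
        metrics["detection_by_stage"][f"specificity_{target}"] = {
            "threshold": cal.threshold,
            "achieved_on_discovery_controls": cal.achieved_specificity,
            "validation_specificity": float((scores_val[~y_val.astype(bool)]
                                             < cal.threshold).mean()),
            "rates": {
                stage: (None if pd.isna(row["rate"]) else {
                    "n": int(row["n"]), "detected": int(row["detected"]),
                    "rate": float(row["rate"]),
                    "ci": [float(row["ci_lower"]), float(row["ci_upper"])]})
                for stage, row in table.iterrows()
            },
        }

    r, p = age_confound_check(scores_val, meta_val["age"])
    metrics["age_confounding"] = {"pearson_r": r, "p_value": p}

    # -- origin model on cancer samples -----------------------------------
    cancer_disc = meta_disc.index[meta_disc["group"].isin(CANCER_GROUPS)]
    cancer_val = meta_val.index[meta_val["group"].isin(CANCER_GROUPS)]
    origin = train_origin_model(
        X_disc.loc[cancer_disc], meta_disc.loc[cancer_disc, "group"],
        cfg.selection, cfg.training, platform_map=pmap, mode=cfg.origin_mode)
    probs, pred = predict_origin(origin, X_val.loc[cancer_val])
    truth_lbl = meta_val.loc[cancer_val, "group"]
    cm = confusion(pred, truth_lbl, list(origin.class_order))
    per_class_auc = {}
    for cls in origin.class_order:
        res = evaluate_scores(probs[cls], (truth_lbl == cls).astype(int),
                              n_boot=cfg.n_boot, seed=eval_seed)
        per_class_auc[cls] = {"auc": res.auc, "ci": [res.ci_lower, res.ci_upper]}
    metrics["origin"] = {
        "mode": cfg.origin_mode,
        "panel_a": origin.panel_a.feature_ids,
        "panel_b": origin.panel_b.feature_ids,
        "accuracy": cm.accuracy,
        "per_class_recall": {c: (None if pd.isna(v) else float(v))
                             for c, v in cm.recall.items()},
        "per_class_auc": per_class_auc,
        "confusion": {t: {c: int(cm.counts.loc[t, c]) for c in cm.counts.columns}
                      for t in cm.counts.index},
    }

    # -- enrichment of the screening panel ---------------------------------
    pw = bundled_pathway_map()
    effective = set(panel.feature_ids) & pw.background
    if effective:
        table = enrich(panel.feature_ids, pw)
        metrics["enrichment"] = {
            "n_panel_annotated": len(effective),
            "significant_pathways": table.loc[table["significant"],
                                              "pathway_name"].tolist(),
            "top": table.head(5)[["pathway_name", "k", "K", "p_value", "q_value"]]
                   .to_dict(orient="records"),
        }
    else:
        metrics["enrichment"] = {"n_panel_annotated": 0, "significant_pathways": [],
                                 "top": []}

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        uio.write_cohort(matrices, meta, outdir / "cohort", truth)
        panel.to_tsv(outdir / "screening_panel.tsv")
        origin.panel_a.to_tsv(outdir / "origin_panel_a.tsv")
        origin.panel_b.to_tsv(outdir / "origin_panel_b.tsv")
        uio.dump_json(metrics, outdir / "metrics.json")
    return metrics
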