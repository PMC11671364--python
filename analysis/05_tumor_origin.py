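"""Two-stage tumor-origin model: LC vs non-LC, then GC vs CRC.

Selects the two disjoint panels, composes the hierarchical three-class
predictor, and evaluates accuracy, per-class OvR AUC and the confusion
matrix on the validation cancers.  Writes results/origin/.
"""

import pandas as pd

from common import RESULTS, analysis_config
from urometab.evaluation import confusion, evaluate_scores
from urometab.io import dump_json
from urometab.origin import CLASS_ORDER, predict_origin, train_origin_model
from urometab.pipeline import derive_seed, platform_map_from_columns


def main() -> None:
    cfg = analysis_config().reseeded()
    X = pd.read_csv(RESULTS / "preprocessed" / "features_scaled.tsv", sep="\t",
                    index_col="sample_id")
    meta = pd.read_csv(RESULTS / "preprocessed" / "metadata.tsv", sep="\t",
                       index_col="sample_id")
    cancers = meta["group"].isin(["LC", "GC", "CRC"])
    disc = meta.index[(meta["cohort"] == "discovery") & cancers]
    val = meta.index[(meta["cohort"] == "validation") & cancers]

    model = train_origin_model(
        X.loc[disc], meta.loc[disc, "group"], cfg.selection, cfg.training,
        platform_map=platform_map_from_columns(X.columns), mode=cfg.origin_mode)
    print(f"panel A (LC vs non-LC): {model.panel_a.feature_ids}")
    print(f"panel B (GC vs CRC):    {model.panel_b.feature_ids}")

    probs, pred = predict_origin(model, X.loc[val])
    truth = meta.loc[val, "group"]
    cm = confusion(pred, truth, list(CLASS_ORDER))
    print(f"validation accuracy: {cm.accuracy:.2f}; "
          f"per-class detection rate: "
          + ", ".join(f"{c} {cm.recall[c]:.2f}" for c in CLASS_ORDER))

    eval_seed = derive_seed(cfg.seed, "evaluation")
    out = {
        "accuracy": cm.accuracy,
        "panel_a": model.panel_a.feature_ids,
        "panel_b": model.panel_b.feature_ids,
        "confusion": {t: {c: int(cm.counts.loc[t, c]) for c in cm.counts.columns}
                      for t in cm.counts.index},
        "per_class_auc": {},
    }
    for cls in CLASS_ORDER:
        res = evaluate_scores(probs[cls], (truth == cls).astype(int),
                              n_boot=cfg.n_boot, seed=eval_seed)
        out["per_class_auc"][cls] = {"auc": res.auc,
                                     "ci": [res.ci_lower, res.ci_upper]}
        print(f"OvR AUC {cls}: {res.auc:.3f} "
              f"(95% CI {res.ci_lower:.3f}-{res.ci_upper:.3f})")

    outdir = RESULTS / "origin"
    outdir.mkdir(parents=True, exist_ok=True)
    model.panel_a.to_tsv(outdir / "panel_a.tsv")
    model.panel_b.to_tsv(outdir / "panel_b.tsv")
    dump_json(out, outdir / "origin_metrics.json")


if __name__ == "__main__":
    main()
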