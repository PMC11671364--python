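"""Train the screening SVM, calibrate specificity thresholds, evaluate.

Reports validation AUC (cancer vs HC and vs all non-cancer) with bootstrap
CIs, stage-stratified detection rates at 95% and 99% specificity, and the
age-confounding check.  Writes results/screening/.
"""

import json

import pandas as pd

from common import RESULTS, analysis_config
from urometab.evaluation import evaluate_scores
from urometab.io import dump_json
from urometab.panels import Panel
from urometab.pipeline import derive_seed
from urometab.screening import (age_confound_check, calibrate,
                                detection_rate_by_stage, train_screening_model)


def main() -> None:
    cfg = analysis_config().reseeded()
    X = pd.read_csv(RESULTS / "preprocessed" / "features_scaled.tsv", sep="\t",
                    index_col="sample_id")
    meta = pd.read_csv(RESULTS / "preprocessed" / "metadata.tsv", sep="\t",
                       index_col="sample_id")
    panel = Panel.from_tsv(RESULTS / "panels" / "screening_panel.tsv")
    disc = meta.index[meta["cohort"] == "discovery"]
    val = meta.index[meta["cohort"] == "validation"]
    y = meta["group"].isin(["LC", "GC", "CRC"]).astype(int)

    model = train_screening_model(X.loc[disc, panel.feature_ids], y.loc[disc],
                                  cfg.training)
    scores_val = model.scores(X.loc[val])
    eval_seed = derive_seed(cfg.seed, "evaluation")

    out = {"cv_auc": model.cv_best_auc, "panel_size": len(panel)}
    hc = meta.loc[val, "group"] == "HC"
    cancer = y.loc[val] == 1
    for name, mask in (("cancer_vs_hc", cancer | hc),
                       ("cancer_vs_noncancer", pd.Series(True, index=val))):
        res = evaluate_scores(scores_val[mask.to_numpy()],
                              y.loc[val][mask.to_numpy()],
                              n_boot=cfg.n_boot, seed=eval_seed)
        out[f"auc_validation_{name}"] = {
            "auc": res.auc, "ci": [res.ci_lower, res.ci_upper]}
        print(f"validation AUC ({name}): {res.auc:.3f} "
              f"(95% CI {res.ci_lower:.3f}-{res.ci_upper:.3f})")

    controls = X.loc[disc][~y.loc[disc].astype(bool)]
    out["detection_by_stage"] = {}
    for target in cfg.target_specificities:
        cal = calibrate(model, controls, target)
        table = detection_rate_by_stage(scores_val, cal.threshold, meta.loc[val])
        out["detection_by_stage"][str(target)] = json.loads(
            table.to_json(orient="index"))
        rates = " ".join(f"{s}:{100 * table.loc[s, 'rate']:.0f}%"
                         for s in ("I", "II", "III", "IV")
                         if table.loc[s, "n"] > 0)
        print(f"detection at {target:.0%} specificity by stage: {rates}")

    r, p = age_confound_check(scores_val, meta.loc[val, "age"])
    out["age_confounding"] = {"pearson_r": r, "p_value": p}
    print(f"score-age correlation: R = {r:.2f}, P = {p:.2g}")

    outdir = RESULTS / "screening"
    outdir.mkdir(parents=True, exist_ok=True)
    dump_json(out, outdir / "screening_metrics.json")


if __name__ == "__main__":
    main()
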