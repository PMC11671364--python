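"""Preprocess the simulated cohort: filter, impute, MSTUS, QC-correct, scale.

Reads results/cohort/, writes the combined preprocessed feature table and a
per-platform preprocessing report under results/preprocessed/.
"""

import json

from common import RESULTS, analysis_config
from urometab.io import read_cohort
from urometab.preprocess import preprocess_cohort


def main() -> None:
    cfg = analysis_config().reseeded()
    matrices, meta = read_cohort(RESULTS / "cohort")
    X, reports = preprocess_cohort(matrices, meta, cfg.preprocess)

    outdir = RESULTS / "preprocessed"
    outdir.mkdir(parents=True, exist_ok=True)
    X.to_csv(outdir / "features_scaled.tsv", sep="\t")
    meta.to_csv(outdir / "metadata.tsv", sep="\t")
    (outdir / "report.json").write_text(
        json.dumps({p: r.to_dict() for p, r in reports.items()}, indent=1,
                   sort_keys=True))

    for p, r in sorted(reports.items()):
        rsd = (f"QC RSD {r.qc_rsd_before.median():.3f} -> "
               f"{r.qc_rsd_after.median():.3f}"
               if r.qc_rsd_before is not None else "no QC correction")
        print(f"{p}: dropped {len(r.dropped_features)} features "
              f"below 80% detection; {rsd}")
    print(f"combined matrix: {X.shape[0]} subjects x {X.shape[1]} features "
          f"-> {outdir}")


if __name__ == "__main__":
    main()
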