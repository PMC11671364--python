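"""Simulate the synthetic multi-platform urinary-metabolomics cohort.

Writes per-platform feature tables (TSV, empty cell = missing), sample
annotations (batch, QC flag), clinical metadata and the ground-truth record
under results/cohort/.
"""

from common import RESULTS, analysis_config
from urometab.cohort import generate_cohort
from urometab.io import write_cohort


def main() -> None:
    cfg = analysis_config().reseeded()
    matrices, meta, truth = generate_cohort(cfg.cohort)
    outdir = RESULTS / "cohort"
    write_cohort(matrices, meta, outdir, truth)

    n_cancer = int(meta["group"].isin(["LC", "GC", "CRC"]).sum())
    print(f"cohort: {len(meta)} subjects "
          f"({n_cancer} cancer, {len(meta) - n_cancer} non-cancer), "
          f"{sum(m.values.shape[1] for m in matrices.values())} features "
          f"across {len(matrices)} platforms")
    print(f"discovery/validation: "
          f"{(meta['cohort'] == 'discovery').sum()}/{(meta['cohort'] == 'validation').sum()}")
    print(f"planted effects: {len(truth.planted)} "
          f"({sorted(truth.planted_feature_ids())})")
    print(f"written to {outdir}")


if __name__ == "__main__":
    main()
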