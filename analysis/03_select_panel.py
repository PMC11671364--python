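"""Select the pan-cancer screening panel by ensemble LASSO, per platform.

Reads results/preprocessed/, writes results/panels/screening_panel.tsv.
"""

import pandas as pd

from common import RESULTS, analysis_config
from urometab.panels import select_per_platform_and_merge
from urometab.pipeline import platform_map_from_columns


def main() -> None:
    cfg = analysis_config().reseeded()
    X = pd.read_csv(RESULTS / "preprocessed" / "features_scaled.tsv", sep="\t",
                    index_col="sample_id")
    meta = pd.read_csv(RESULTS / "preprocessed" / "metadata.tsv", sep="\t",
                       index_col="sample_id")
    disc = meta.index[meta["cohort"] == "discovery"]
    y = meta.loc[disc, "group"].isin(["LC", "GC", "CRC"]).astype(int)
    pmap = platform_map_from_columns(X.columns)
    views = {n: X.loc[disc, [c for c in X.columns if pmap[c] == n]]
             for n in sorted(set(pmap.values()))}

    panel = select_per_platform_and_merge(views, y, cfg.selection,
                                          label="screening")
    outdir = RESULTS / "panels"
    outdir.mkdir(parents=True, exist_ok=True)
    panel.to_tsv(outdir / "screening_panel.tsv")

    print(f"screening panel: {len(panel)} metabolites at frequency >= "
          f"{cfg.selection.frequency_threshold} over {cfg.selection.n_rounds} rounds")
    print(panel.entries.to_string(index=False))


if __name__ == "__main__":
    main()
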