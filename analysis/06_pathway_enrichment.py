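"""Over-representation of the screening panel against the bundled pathway map.

Reads results/panels/screening_panel.tsv, writes results/enrichment/.
"""

from common import RESULTS
from urometab.enrichment import bundled_pathway_map, enrich
from urometab.panels import Panel


def main() -> None:
    panel = Panel.from_tsv(RESULTS / "panels" / "screening_panel.tsv")
    pmap = bundled_pathway_map()
    table = enrich(panel.feature_ids, pmap, alpha=0.05)

    outdir = RESULTS / "enrichment"
    outdir.mkdir(parents=True, exist_ok=True)
    table.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)

    sig = table[table["significant"]]
    print(f"{len(panel)} panel metabolites, "
          f"{table['n'].iloc[0] if len(table) else 0} annotated in the map")
    if sig.empty:
        print("no pathway significant at raw p < 0.05")
    else:
        print("significant pathways (raw p < 0.05):")
        for _, row in sig.iterrows():
            print(f"  {row['pathway_name']}: k={row['k']}/{row['K']}, "
                  f"p={row['p_value']:.4f}, q={row['q_value']:.4f}")


if __name__ == "__main__":
    main()
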