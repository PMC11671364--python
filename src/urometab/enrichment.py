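"""Pathway over-representation analysis for metabolite panels.

One-sided hypergeometric test per pathway: with a background universe of N
annotated metabolites of which K belong to the pathway, and a panel of n
annotated metabolites of which k hit the pathway, the p-value is
P(X >= k) for X ~ Hypergeometric(N, K, n).  Benjamini-Hochberg q-values
are reported alongside, but the significance flag follows the raw p-value
threshold (default 0.05).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)


@dataclass
class PathwayMap:
    """pathway_id -> member metabolites, plus the annotated background."""

    members: dict[str, frozenset]
    names: dict[str, str]
    background: frozenset

    def __post_init__(self):
        for pid, mem in self.members.items():
            if not mem:
                raise ValueError(f"pathway {pid!r} has no members")
            if not mem <= self.background:
                raise ValueError(f"pathway {pid!r} has members outside the background")

    @classmethod
    def from_tsv(cls, members_path, names_path=None,
                 background: set | None = None) -> "PathwayMap":
        """Two-column TSV (pathway_id, metabolite_id); optional names table."""
        tab = pd.read_csv(members_path, sep="\t")
        if list(tab.columns[:2]) != ["pathway_id", "metabolite_id"]:
            tab.columns = ["pathway_id", "metabolite_id"] + list(tab.columns[2:])
        members = {
            pid: frozenset(sub["metabolite_id"])
            for pid, sub in tab.groupby("pathway_id", sort=True)
        }
        bg = frozenset(background) if background is not None else frozenset(
            tab["metabolite_id"])
        names = {pid: pid for pid in members}
        if names_path is not None:
            nt = pd.read_csv(names_path, sep="\t")
            names.update(dict(zip(nt.iloc[:, 0], nt.iloc[:, 1])))
        return cls(members=members, names=names, background=bg)


def bundled_pathway_map() -> PathwayMap:
    """The synthetic pathway map shipped with the package.

    A hand-built, synthetic KEGG-style annotation of the synthetic cohort's
    metabolite namespace (15 pathways over ~80 of the 360 features); it
    exists so that enrichment is exercisable end-to-end without live
    database access and carries no real biochemistry.
    """
    data = resources.files("urometab") / "data"
    return PathwayMap.from_tsv(
        data / "synthetic_pathway_members.tsv",
        data / "synthetic_pathway_names.tsv",
    )


def enrich(panel_features, pathway_map: PathwayMap, alpha: float = 0.05,
           background: set | None = None) -> pd.DataFrame:
    """Over-representation of a panel against every pathway in the map.

    Panel metabolites without annotation are dropped (count logged).
    Returns one row per pathway: k, K, n, N, p_value, q_value, significant,
    sorted by p-value ascending.
    """
    bg = frozenset(background) if background is not None else pathway_map.background
    panel = set(panel_features)
    effective = panel & bg
    dropped = len(panel) - len(effective)
    if dropped:
        log.info("dropped %d panel metabolites without annotation", dropped)
    if not effective:
        raise ValueError("no panel metabolite is in the annotated background")
    N = len(bg)
    n = len(effective)
    rows = []
    for pid in sorted(pathway_map.members):
        mem = pathway_map.members[pid] & bg
        K = len(mem)
        if K == 0:
            continue
        k = len(effective & mem)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append((pid, pathway_map.names.get(pid, pid), k, K, n, N, min(p, 1.0)))
    table = pd.DataFrame(
        rows, columns=["pathway_id", "pathway_name", "k", "K", "n", "N", "p_value"])
    table["q_value"] = multipletests(table["p_value"], method="fdr_bh")[1]
    table["significant"] = table["p_value"] < alpha
    return table.sort_values(
        ["p_value", "pathway_id"], kind="mergesort").reset_index(drop=True)
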