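"""Reading and writing the pipeline's plain-text formats.

Feature tables are TSV/CSV with the sample identifier in the first column
and metabolite IDs as the header; an empty cell (or NA) is a missing
value.  Per-platform sample annotations (batch, QC flag) travel in a
sidecar table so the feature table stays a pure samples x metabolites
matrix.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import FeatureMatrix, TruthRecord


def _sep_for(path: Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_feature_table(
    path,
    platform: str | None = None,
    annotations: pd.DataFrame | None = None,
) -> FeatureMatrix:
    """Parse a feature table; validates IDs and positivity with locations.

    ``annotations`` (index sample_id, columns batch and is_qc) may come from
    ``read_sample_annotations``; without it every row is treated as a
    subject sample in a single batch.
    """
    path = Path(path)
    tab = pd.read_csv(path, sep=_sep_for(path), dtype={0: str})
    sid_col = tab.columns[0]
    dup = tab[sid_col][tab[sid_col].duplicated()]
    if not dup.empty:
        line = int(dup.index[0]) + 2  # header + 1-based
        raise ValueError(f"{path}: duplicate sample id {dup.iloc[0]!r} at line {line}")
    feats = list(tab.columns[1:])
    if len(set(feats)) != len(feats):
        seen = set()
        dup_f = next(f for f in feats if f in seen or seen.add(f))
        raise ValueError(f"{path}: duplicate feature id {dup_f!r}")
    values = tab.set_index(sid_col)[feats].astype(float)
    neg = values < 0
    if neg.any().any():
        col = values.columns[neg.any(axis=0)][0]
        row = values.index[neg[col]][0]
        line = list(values.index).index(row) + 2
        raise ValueError(f"{path}: negative intensity for {row!r}/{col} at line {line}")
    values.index.name = "sample_id"
    if annotations is not None:
        ann = annotations.loc[values.index]
        batch = ann["batch"].astype(str)
        is_qc = ann["is_qc"].astype(bool)
    else:
        batch = pd.Series("B1", index=values.index, name="batch")
        is_qc = pd.Series(False, index=values.index, name="is_qc")
    return FeatureMatrix(platform or path.stem, values, batch, is_qc)


def write_feature_table(fm: FeatureMatrix, path) -> None:
    path = Path(path)
    out = fm.values.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep=_sep_for(path), na_rep="")


def write_sample_annotations(fm: FeatureMatrix, path) -> None:
    ann = pd.DataFrame({"batch": fm.batch, "is_qc": fm.is_qc})
    ann.index.name = "sample_id"
    ann.to_csv(path, sep="\t")


def read_sample_annotations(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def write_metadata(meta: pd.DataFrame, path) -> None:
    out = meta.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_metadata(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def write_cohort(matrices: dict[str, FeatureMatrix], meta: pd.DataFrame,
                 outdir, truth: TruthRecord | None = None) -> None:
    """Write per-platform feature + annotation tables, metadata and truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for platform, fm in matrices.items():
        write_feature_table(fm, outdir / f"{platform}_features.tsv")
        write_sample_annotations(fm, outdir / f"{platform}_samples.tsv")
    write_metadata(meta, outdir / "metadata.tsv")
    if truth is not None:
        record = {
            "planted": [
                {
                    "feature_id": e.feature_id,
                    "contrast": list(e.shifted_groups()),
                    "base_log2_effect": e.base_log2_effect,
                    "direction": e.direction,
                    "stage_multipliers": e.stage_multipliers,
                }
                for e in truth.planted
            ],
            "dilution": {k: float(v) for k, v in truth.dilution.items()},
            "batch_effects": {
                p: {b: [float(x) for x in row]
                    for b, row in be.iterrows()}
                for p, be in truth.batch_effects.items()
            },
        }
        (outdir / "truth.json").write_text(json.dumps(record, indent=1, sort_keys=True))


def read_cohort(indir) -> tuple[dict[str, FeatureMatrix], pd.DataFrame]:
    indir = Path(indir)
    meta = read_metadata(indir / "metadata.tsv")
    matrices = {}
    for fpath in sorted(indir.glob("*_features.tsv")):
        platform = fpath.name[: -len("_features.tsv")]
        ann = read_sample_annotations(indir / f"{platform}_samples.tsv")
        matrices[platform] = read_feature_table(fpath, platform, ann)
    return matrices, meta


def dump_json(obj, path) -> None:
    """Deterministic JSON: sorted keys, fixed float formatting."""
    Path(path).write_text(json.dumps(_round_floats(obj), indent=1, sort_keys=True) + "\n")


def _round_floats(obj, ndigits: int = 6):
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (float, np.floating)):
        if np.isnan(obj):
            return None
        return round(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj
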