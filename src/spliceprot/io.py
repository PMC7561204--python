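"""TSV readers and writers for every table interface.

All tables are UTF-8, tab-separated with a header row; floats are
serialised with six significant digits and rows are written in a stable
sort order so reruns produce byte-identical files.  Readers validate the
required columns and value domains and report offending row numbers.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .core import AgeBin, Effect, Mechanism, TissueSchema
from .errors import ValidationError
from .evolution import CLADE_LADDER, SEARCH_MODES

FLOAT_FORMAT = "%.6g"

_TABLE_COLUMNS = {
    "events": ["event_id", "gene_id", "mechanism", "effect", "side_a_len",
               "side_b_len", "homologous_flag", "age_label"],
    "detections": ["peptide", "gene_id", "event_id", "side", "experiment_id", "tissue"],
    "reads": ["event_id", "group", "side", "reads"],
    "scores": ["region_id", "position", "score"],
    "homology": ["exon_id", "mode", "hit_species", "hit_clade", "insertions"],
    "schema": ["tissue", "group", "n_experiments"],
}


def _read(path: str | Path, kind: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _TABLE_COLUMNS[kind] if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    return df


def _bad_rows(mask: pd.Series, path, what: str) -> None:
    if mask.any():
        rows = [int(i) + 2 for i in mask[mask].index[:5]]  # 1-based incl. header
        raise ValidationError(f"{path}: {what} (rows {rows}{'...' if mask.sum() > 5 else ''})")


def read_events(path: str | Path) -> pd.DataFrame:
    df = _read(path, "events")
    mechs = {m.value for m in Mechanism}
    effs = {e.value for e in Effect}
    ages = {a.value for a in AgeBin} | {""}
    _bad_rows(~df["mechanism"].isin(mechs), path, "unknown mechanism")
    _bad_rows(~df["effect"].isin(effs), path, "unknown effect")
    _bad_rows(~df["age_label"].isin(ages), path, "unknown age label")
    for col in ("side_a_len", "side_b_len"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
        _bad_rows(df[col].isna() | (df[col] < 0), path, f"invalid {col}")
        df[col] = df[col].astype(int)
    df["homologous_flag"] = df["homologous_flag"].str.lower().isin(["true", "1", "yes"])
    return df


def read_detections(path: str | Path) -> pd.DataFrame:
    df = _read(path, "detections")
    _bad_rows(df["peptide"] == "", path, "empty peptide")
    _bad_rows(df["experiment_id"] == "", path, "empty experiment id")
    return df


def read_reads(path: str | Path) -> pd.DataFrame:
    df = _read(path, "reads")
    df["reads"] = pd.to_numeric(df["reads"], errors="coerce")
    _bad_rows(df["reads"].isna() | (df["reads"] < 0), path, "invalid read count")
    return df


def read_scores(path: str | Path) -> pd.DataFrame:
    df = _read(path, "scores")
    df["position"] = pd.to_numeric(df["position"], errors="coerce")
    df["score"] = pd.to_numeric(df["score"], errors="coerce")
    _bad_rows(df["position"].isna() | (df["position"] < 1), path, "invalid position")
    _bad_rows(df["score"].isna() | (df["score"] < 0) | (df["score"] > 1), path,
              "score outside [0,1]")
    df["position"] = df["position"].astype(int)
    return df


def read_homology(path: str | Path) -> pd.DataFrame:
    df = _read(path, "homology")
    _bad_rows(~df["mode"].isin(SEARCH_MODES), path, "unknown search mode")
    _bad_rows(~df["hit_clade"].isin(CLADE_LADDER), path, "unknown clade")
    df["insertions"] = pd.to_numeric(df["insertions"], errors="coerce")
    _bad_rows(df["insertions"].isna() | (df["insertions"] < 0), path,
              "invalid insertion count")
    df["insertions"] = df["insertions"].astype(int)
    return df


def read_schema(path: str | Path) -> TissueSchema:
    df = _read(path, "schema")
    df["n_experiments"] = pd.to_numeric(df["n_experiments"], errors="coerce")
    _bad_rows(df["n_experiments"].isna() | (df["n_experiments"] < 1), path,
              "invalid experiment count")
    dup = df["tissue"].duplicated()
    _bad_rows(dup, path, "duplicate tissue")
    return TissueSchema(
        groups=dict(zip(df["tissue"], df["group"])),
        n_experiments=dict(zip(df["tissue"], df["n_experiments"].astype(int))),
    )


def schema_to_frame(schema: TissueSchema) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "tissue": schema.tissues,
            "group": [schema.groups[t] for t in schema.tissues],
            "n_experiments": [schema.n_experiments[t] for t in schema.tissues],
        }
    )


def write_tsv(
    df: pd.DataFrame,
    path: str | Path,
    sort_by: Optional[Iterable[str]] = None,
) -> Path:
    """Write a table deterministically (stable sort, fixed float format)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = df.copy()
    keys = list(sort_by) if sort_by else [c for c in out.columns if out[c].dtype == object]
    if keys:
        out = out.sort_values(keys, kind="mergesort")
    out.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
    return path
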