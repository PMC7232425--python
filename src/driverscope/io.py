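"""Tab-separated table I/O with validation.

All tables are UTF-8 TSV.  Feature tables: header row of feature ids, first
column station id, nonnegative numeric cells, no missing values.  Station
tables: first column station id, a ``region`` column, numeric covariates
and the two taxon fractions.  Parse errors name the offending identifier
and the 1-based line number.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import TAXON_COLUMNS

__all__ = [
    "read_feature_table",
    "write_feature_table",
    "read_station_table",
    "write_station_table",
    "read_mapping",
    "read_hierarchy",
]


class TableParseError(ValueError):
    """Malformed input table (ragged rows, duplicates, bad values)."""


def _check_unique(ids: pd.Index, what: str, path: Path) -> None:
    dup = ids[ids.duplicated()]
    if len(dup):
        raise TableParseError(f"{path}: duplicated {what} {dup[0]!r}")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:
        raise TableParseError(f"{path}: ragged or malformed TSV ({exc})") from exc
    _check_unique(df.index, "station id", path)
    _check_unique(df.columns, "feature id", path)
    if df.isna().any().any():
        i, j = np.argwhere(df.isna().to_numpy())[0]
        raise TableParseError(
            f"{path}: missing value at line {i + 2}, feature {df.columns[j]!r}"
        )
    try:
        vals = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise TableParseError(f"{path}: non-numeric cell in feature table ({exc})") from exc
    if (vals < 0).any():
        i, j = np.argwhere(vals < 0)[0]
        raise TableParseError(
            f"{path}: negative count {vals[i, j]} at line {i + 2} "
            f"(station {df.index[i]!r}), feature {df.columns[j]!r}"
        )
    df.index.name = "station_id"
    df.columns.name = "feature_id"
    return df


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    table.rename_axis("station_id").to_csv(path, sep="\t")


def read_station_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:
        raise TableParseError(f"{path}: ragged or malformed TSV ({exc})") from exc
    _check_unique(df.index, "station id", path)
    if "region" not in df.columns:
        raise TableParseError(f"{path}: station table needs a 'region' column")
    numeric = [c for c in df.columns if c != "region"]
    if df[numeric].isna().any().any():
        bad = df[numeric].isna().any()
        raise TableParseError(
            f"{path}: missing values in column(s) {list(bad[bad].index)}"
        )
    for col in TAXON_COLUMNS:
        if col in df.columns:
            v = df[col].to_numpy(dtype=float)
            if ((v < 0) | (v > 1)).any():
                raise TableParseError(f"{path}: {col} values must lie in [0, 1]")
    df.index.name = "station_id"
    return df


def write_station_table(cov: pd.DataFrame, path: str | Path) -> None:
    cov.rename_axis("station_id").to_csv(path, sep="\t")


def read_mapping(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if not {"pfam_id", "ko_id"} <= set(df.columns):
        raise TableParseError(f"{path}: mapping needs columns pfam_id, ko_id")
    return df[["pfam_id", "ko_id"]]


def read_hierarchy(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    need = {"ko_id", "pathway", "category"}
    if not need <= set(df.columns):
        raise TableParseError(f"{path}: hierarchy needs columns {sorted(need)}")
    return df[["ko_id", "pathway", "category"]]
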