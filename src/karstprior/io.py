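"""Readers, writers, and validation for the three tabular inputs.

All tables travel as pandas DataFrames with fixed column schemas:

* caves:       ``cave_id, name, x, y, length_m, season``
* occurrences: ``cave_id, species_id, troglobiont``
* impacts:     ``impact_type, x, y``

Coordinates are planar meters in a projected system; CSV files are
comma-separated UTF-8 with a header row and ``.`` decimals.  Validation is
total: a file either loads completely or raises :class:`ValidationError`
naming the offending row or identifier — rows are never silently dropped.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .config import IMPACT_TYPES, SEASONS

CAVE_COLUMNS = ["cave_id", "name", "x", "y", "length_m", "season"]
OCCURRENCE_COLUMNS = ["cave_id", "species_id", "troglobiont"]
IMPACT_COLUMNS = ["impact_type", "x", "y"]

_BOOL_STRINGS = {"true": True, "1": True, "false": False, "0": False}


class ValidationError(ValueError):
    """An input table violates its schema or invariants."""


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{what}: missing column(s) {missing}")


def _numeric(df: pd.DataFrame, column: str, what: str) -> pd.Series:
    """Parse a column as float, reporting the first bad row (1-based data row)."""
    values = pd.to_numeric(df[column], errors="coerce")
    raw_na = df[column].isna()
    bad = (values.isna() & ~raw_na) | raw_na
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
        raise ValidationError(
            f"{what}: non-numeric value {df[column].iloc[row - 1]!r} "
            f"in column '{column}' at data row {row}"
        )
    if not np.isfinite(values.to_numpy(dtype=float)).all():
        row = int(np.flatnonzero(~np.isfinite(values.to_numpy(dtype=float)))[0]) + 1
        raise ValidationError(
            f"{what}: non-finite value in column '{column}' at data row {row}"
        )
    return values.astype(float)


def _parse_bool(series: pd.Series, what: str) -> pd.Series:
    out = []
    for i, raw in enumerate(series):
        key = str(raw).strip().lower()
        if key not in _BOOL_STRINGS:
            raise ValidationError(
                f"{what}: cannot parse boolean {raw!r} at data row {i + 1} "
                f"(accepted: true/false/1/0, case-insensitive)"
            )
        out.append(_BOOL_STRINGS[key])
    return pd.Series(out, index=series.index, dtype=bool)


# ---------------------------------------------------------------------------
# caves
# ---------------------------------------------------------------------------

def validate_caves(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a cave inventory table, returning a normalized copy."""
    _require_columns(df, CAVE_COLUMNS, "caves")
    df = df[CAVE_COLUMNS].copy()
    df["cave_id"] = df["cave_id"].astype(str)
    df["name"] = df["name"].astype(str)
    dup = df["cave_id"][df["cave_id"].duplicated()]
    if not dup.empty:
        raise ValidationError(f"caves: duplicate cave_id {dup.iloc[0]!r}")
    df["x"] = _numeric(df, "x", "caves")
    df["y"] = _numeric(df, "y", "caves")
    df["length_m"] = _numeric(df, "length_m", "caves")
    if (df["length_m"] <= 0).any():
        bad = df.loc[df["length_m"] <= 0, "cave_id"].iloc[0]
        raise ValidationError(f"caves: non-positive length_m for cave {bad!r}")
    df["season"] = df["season"].astype(str).str.lower()
    unknown = set(df["season"]) - set(SEASONS)
    if unknown:
        raise ValidationError(
            f"caves: invalid season value(s) {sorted(unknown)}; allowed: {SEASONS}"
        )
    return df.reset_index(drop=True)


def load_caves(path: str | Path) -> pd.DataFrame:
    """Read and validate ``caves.csv`` (row order preserved)."""
    return validate_caves(pd.read_csv(path, dtype=str))


def write_caves(df: pd.DataFrame, path: str | Path) -> None:
    validate_caves(df).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# occurrences
# ---------------------------------------------------------------------------

def validate_occurrences(
    df: pd.DataFrame,
    caves: pd.DataFrame | None = None,
    duplicates: str = "error",
) -> pd.DataFrame:
    """Validate a long-format occurrence table.

    Parameters
    ----------
    caves:
        Optional cave table; if given, every ``cave_id`` must resolve.
    duplicates:
        ``"error"`` rejects duplicate (cave_id, species_id) pairs,
        ``"drop"`` deduplicates them (flags must still be consistent).
    """
    _require_columns(df, OCCURRENCE_COLUMNS, "occurrences")
    df = df[OCCURRENCE_COLUMNS].copy()
    df["cave_id"] = df["cave_id"].astype(str)
    df["species_id"] = df["species_id"].astype(str)
    if df["troglobiont"].dtype != bool:
        df["troglobiont"] = _parse_bool(df["troglobiont"], "occurrences")

    flags = df.groupby("species_id")["troglobiont"].nunique()
    inconsistent = flags[flags > 1]
    if not inconsistent.empty:
        raise ValidationError(
            "occurrences: species flagged both troglobiont and non-troglobiont: "
            f"{inconsistent.index[0]!r}"
        )

    dup_mask = df.duplicated(subset=["cave_id", "species_id"])
    if dup_mask.any():
        if duplicates == "error":
            pair = df.loc[dup_mask, ["cave_id", "species_id"]].iloc[0]
            raise ValidationError(
                f"occurrences: duplicate record ({pair.cave_id!r}, {pair.species_id!r})"
            )
        if duplicates != "drop":
            raise ValueError(f"duplicates must be 'error' or 'drop', got {duplicates!r}")
        df = df[~dup_mask]

    if caves is not None:
        known = set(caves["cave_id"])
        orphan = set(df["cave_id"]) - known
        if orphan:
            raise ValidationError(
                f"occurrences: cave_id(s) absent from cave table: {sorted(orphan)[:5]}"
            )
    return df.reset_index(drop=True)


def load_occurrences(
    path: str | Path,
    caves: pd.DataFrame | None = None,
    duplicates: str = "error",
) -> pd.DataFrame:
    return validate_occurrences(pd.read_csv(path, dtype=str), caves, duplicates)


def write_occurrences(df: pd.DataFrame, path: str | Path) -> None:
    out = validate_occurrences(df).copy()
    out["troglobiont"] = out["troglobiont"].map({True: "true", False: "false"})
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# impacts
# ---------------------------------------------------------------------------

def validate_impacts(df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, IMPACT_COLUMNS, "impacts")
    df = df[IMPACT_COLUMNS].copy()
    df["impact_type"] = df["impact_type"].astype(str)
    unknown = set(df["impact_type"]) - set(IMPACT_TYPES)
    if unknown:
        raise ValidationError(
            f"impacts: unknown impact type(s) {sorted(unknown)}; "
            f"allowed values: {list(IMPACT_TYPES)}"
        )
    df["x"] = _numeric(df, "x", "impacts")
    df["y"] = _numeric(df, "y", "impacts")
    return df.reset_index(drop=True)


def load_impacts(path: str | Path) -> pd.DataFrame:
    return validate_impacts(pd.read_csv(path, dtype=str))


def write_impacts(df: pd.DataFrame, path: str | Path) -> None:
    validate_impacts(df).to_csv(path, index=False)
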