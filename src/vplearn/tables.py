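"""Readers and writers for the package's tabular formats.

All tables are comma-separated UTF-8 with a mandatory header row and "."
decimals. Readers fail loudly: missing columns, unparseable values and empty
files raise with the offending column or row named.
"""
from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = [
    "TRIAL_COLUMNS",
    "THRESHOLD_COLUMNS",
    "SchemaError",
    "read_trial_table",
    "write_trial_table",
    "read_threshold_table",
    "write_threshold_table",
]

TRIAL_COLUMNS = [
    "participant", "session", "task", "stimulus", "block",
    "trial", "level", "correct", "reversal",
]
THRESHOLD_COLUMNS = [
    "participant", "session", "task", "stimulus", "block", "measure",
    "threshold", "spread",
]

_BOOL_MAP = {
    "true": True, "false": False, "1": True, "0": False,
    "t": True, "f": False, "yes": True, "no": False,
}


class SchemaError(ValueError):
    pass


def _check_header(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s) {', '.join(missing)}"
        )


def _parse_bool_column(df: pd.DataFrame, column: str, path) -> pd.Series:
    def parse(value, row):
        if isinstance(value, bool):
            return value
        key = str(value).strip().lower()
        if key not in _BOOL_MAP:
            raise SchemaError(
                f"{path}: non-boolean value {value!r} in column {column!r}, row {row}"
            )
        return _BOOL_MAP[key]

    return pd.Series(
        [parse(v, i + 2) for i, v in enumerate(df[column])],  # +2: header is row 1
        index=df.index, dtype=bool,
    )


def read_trial_table(path) -> pd.DataFrame:
    """Read and validate a trial table; row order is preserved."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, dtype={"task": str, "stimulus": str})
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: file is empty") from None
    if df.empty:
        raise SchemaError(f"{path}: table has a header but no rows")
    _check_header(df, TRIAL_COLUMNS, path)
    df["correct"] = _parse_bool_column(df, "correct", path)
    df["reversal"] = _parse_bool_column(df, "reversal", path)
    for column in ("participant", "session", "block", "trial"):
        df[column] = df[column].astype(int)
    df["level"] = df["level"].astype(float)
    return df[TRIAL_COLUMNS]


def write_trial_table(df: pd.DataFrame, path) -> None:
    _check_header(df, TRIAL_COLUMNS, path)
    df[TRIAL_COLUMNS].to_csv(path, index=False)


def read_threshold_table(path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: file is empty") from None
    if df.empty:
        raise SchemaError(f"{path}: table has a header but no rows")
    _check_header(df, THRESHOLD_COLUMNS, path)
    return df[THRESHOLD_COLUMNS]


def write_threshold_table(df: pd.DataFrame, path) -> None:
    _check_header(df, THRESHOLD_COLUMNS, path)
    df[THRESHOLD_COLUMNS].to_csv(path, index=False)
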