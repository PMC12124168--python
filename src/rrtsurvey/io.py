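"""CSV serialization for household and response tables.

Analysis-facing response files must never contain the latent question
assignment; the writer enforces the truth/analysis split and the reader
validates schema and invariants, reporting 1-based line numbers (header is
line 1).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import ANALYSIS_COLUMNS, HOUSEHOLD_COLUMNS, TRUTH_ONLY_COLUMNS

__all__ = [
    "SurveyFormatError",
    "write_households",
    "read_households",
    "write_responses",
    "read_responses",
]

TRUTH_SUFFIX = ".truth.csv"

_CATEGORICAL = {
    "municipality": {"manaus", "carauari"},
    "urbanization": {"rural", "peri_urban", "urban"},
    "residence_status": {"single_sited", "multisited"},
    "management": {"single_adult", "dual_adult"},
    "season": {"dry", "wet"},
}
_COUNT_COLUMNS = ("n_minors", "n_working_adults", "visits_urban", "visits_rural")


class SurveyFormatError(ValueError):
    """Parse or validation failure; message carries the file line number."""


def _fail(path: Path, line: int | None, msg: str) -> None:
    where = f"{path}" if line is None else f"{path}:{line}"
    raise SurveyFormatError(f"{where}: {msg}")


def _read_csv(path: Path, expected_columns: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    except UnicodeDecodeError as exc:
        raise SurveyFormatError(f"{path}: not valid UTF-8 ({exc})") from exc
    if list(df.columns) != expected_columns:
        unknown = [c for c in df.columns if c not in expected_columns]
        missing = [c for c in expected_columns if c not in df.columns]
        _fail(
            path,
            1,
            f"bad header: unknown columns {unknown}, missing columns {missing}"
            if (unknown or missing)
            else f"column order must be {expected_columns}",
        )
    return df


def _parse_counts(df: pd.DataFrame, path: Path) -> pd.DataFrame:
    for col in _COUNT_COLUMNS:
        if col not in df.columns:
            continue
        values = []
        for idx, raw in enumerate(df[col]):
            line = idx + 2
            if raw == "":
                values.append(pd.NA)
                continue
            try:
                v = int(raw)
            except ValueError:
                _fail(path, line, f"{col}: {raw!r} is not an integer")
            if v < 0:
                _fail(path, line, f"{col}: {v} is negative")
            values.append(v)
        df[col] = pd.array(values, dtype="Int64")
    return df


def _finalize_counts(df: pd.DataFrame) -> pd.DataFrame:
    # mandatory counts have been checked complete; plain int64 from here on
    for col in ("n_minors", "n_working_adults"):
        if col in df.columns:
            df[col] = df[col].astype("int64")
    return df


def _validate_common(df: pd.DataFrame, path: Path) -> None:
    for col, levels in _CATEGORICAL.items():
        if col not in df.columns:
            continue
        for idx, raw in enumerate(df[col]):
            if raw not in levels:
                _fail(path, idx + 2, f"{col}: {raw!r} not one of {sorted(levels)}")
    if {"n_minors", "n_working_adults"} <= set(df.columns):
        for col in ("n_minors", "n_working_adults"):
            na_at = df.index[df[col].isna()]
            if len(na_at):
                _fail(path, int(na_at[0]) + 2, f"{col}: missing value")
    # Exclusivity: exactly one visits column applies per row.
    has_u = df["visits_urban"].notna().to_numpy()
    has_r = df["visits_rural"].notna().to_numpy()
    both = np.flatnonzero(has_u & has_r)
    if both.size:
        _fail(path, int(both[0]) + 2, "both visits_urban and visits_rural populated")
    neither = np.flatnonzero(~has_u & ~has_r)
    if neither.size:
        _fail(path, int(neither[0]) + 2, "neither visits_urban nor visits_rural populated")
    urban = (df["urbanization"] == "urban").to_numpy()
    wrong = np.flatnonzero(urban & has_u)
    if wrong.size:
        _fail(path, int(wrong[0]) + 2, "urban household reports visits_urban")
    wrong = np.flatnonzero(~urban & has_r)
    if wrong.size:
        _fail(path, int(wrong[0]) + 2, "non-urban household reports visits_rural")


def write_households(records_df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df = records_df[HOUSEHOLD_COLUMNS]
    df.to_csv(path, index=False, encoding="utf-8")
    return path


def read_households(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = _read_csv(path, HOUSEHOLD_COLUMNS)
    df = _parse_counts(df, path)
    _validate_common(df, path)
    df = _finalize_counts(df)
    dup = df["household_id"].duplicated()
    if dup.any():
        _fail(path, int(np.flatnonzero(dup)[0]) + 2, "duplicate household_id")
    return df


def write_responses(
    responses: pd.DataFrame, path: str | Path, *, truth: bool = False
) -> Path:
    """Write a response table.

    Analysis files are restricted to ``ANALYSIS_COLUMNS`` — the latent
    assignment can only ever reach a file named ``*.truth.csv``.
    """
    path = Path(path)
    if truth:
        if not path.name.endswith(TRUTH_SUFFIX):
            raise SurveyFormatError(
                f"{path}: truth tables must use the {TRUTH_SUFFIX!r} suffix"
            )
        df = responses[ANALYSIS_COLUMNS + TRUTH_ONLY_COLUMNS]
    else:
        if path.name.endswith(TRUTH_SUFFIX):
            raise SurveyFormatError(
                f"{path}: analysis tables must not use the {TRUTH_SUFFIX!r} suffix"
            )
        df = responses[ANALYSIS_COLUMNS]
    df.to_csv(path, index=False, encoding="utf-8")
    return path


def read_responses(path: str | Path, *, truth: bool = False) -> pd.DataFrame:
    path = Path(path)
    columns = ANALYSIS_COLUMNS + TRUTH_ONLY_COLUMNS if truth else ANALYSIS_COLUMNS
    df = _read_csv(path, columns)
    df = _parse_counts(df, path)
    _validate_common(df, path)
    df = _finalize_counts(df)
    for col in ("use", "quantity_category"):
        parsed = []
        for idx, raw in enumerate(df[col]):
            try:
                v = int(raw)
            except ValueError:
                _fail(path, idx + 2, f"{col}: {raw!r} is not an integer")
            if col == "use" and v not in (0, 1):
                _fail(path, idx + 2, f"use: {v} is not binary")
            if v < 0:
                _fail(path, idx + 2, f"{col}: {v} is negative")
            parsed.append(v)
        df[col] = np.asarray(parsed, dtype=int)
    bad = np.flatnonzero((df["quantity_category"].to_numpy() == 0) != (df["use"].to_numpy() == 0))
    if bad.size:
        _fail(path, int(bad[0]) + 2, "quantity_category must be 0 exactly when use is 0")
    if truth:
        for idx, raw in enumerate(df["z"]):
            if raw not in ("sensitive", "nonsensitive"):
                _fail(path, idx + 2, f"z: {raw!r} invalid")
    return df
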