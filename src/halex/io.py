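"""CSV readers/writers with row-level validation.

All tables are UTF-8 CSV with a mandatory header row and dot decimal
separator; ages are decimal years. Malformed rows are reported with their
file line number (header = line 1).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "PanelValidationError",
    "read_panel_csv", "write_panel_csv",
    "read_counts_csv", "write_counts_csv",
    "read_prevalence_csv", "write_prevalence_csv",
    "write_lifetable_csv", "write_hale_csv",
]

PANEL_COLUMNS = ["subject_id", "sex", "entry_age", "entry_state",
                 "exit_age", "exit_kind", "exit_state"]
_EXIT_KINDS = {"alive_observed", "death_exact", "lost"}


class PanelValidationError(ValueError):
    """Raised when a CSV fails validation; message lists offending line numbers."""


def _lines(df: pd.DataFrame, mask) -> list[int]:
    # +2: one for the header, one for 0-based indexing
    return [int(i) + 2 for i in df.index[mask]]


def read_panel_csv(path) -> pd.DataFrame:
    """Read and validate a panel-record CSV (one row per subject)."""
    df = pd.read_csv(path)
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise PanelValidationError(f"{path}: missing columns {missing}")
    errors = []

    dup = df["subject_id"].duplicated(keep=False)
    if dup.any():
        errors.append(f"duplicate subject_id at lines {_lines(df, dup)}")
    bad_sex = ~df["sex"].astype(str).str.lower().isin(["male", "female"])
    if bad_sex.any():
        errors.append(f"sex must be male/female at lines {_lines(df, bad_sex)}")
    bad_kind = ~df["exit_kind"].isin(_EXIT_KINDS)
    if bad_kind.any():
        errors.append(f"unknown exit_kind at lines {_lines(df, bad_kind)}")
    bad_entry = ~df["entry_state"].isin([1, 2])
    if bad_entry.any():
        errors.append(f"entry_state must be 1 or 2 at lines {_lines(df, bad_entry)}")
    alive = df["exit_kind"] == "alive_observed"
    bad_exit = alive & ~df["exit_state"].isin([1, 2])
    if bad_exit.any():
        errors.append(f"exit_state must be 1 or 2 when alive_observed at "
                      f"lines {_lines(df, bad_exit)}")
    closed = df["exit_kind"].isin(["alive_observed", "death_exact"])
    non_mono = closed & (df["exit_age"] <= df["entry_age"])
    if non_mono.any():
        errors.append(f"exit_age must exceed entry_age at lines {_lines(df, non_mono)}")
    if errors:
        raise PanelValidationError(f"{path}: " + "; ".join(errors))

    df["exit_state"] = df["exit_state"].astype("Int64")
    df["sex"] = df["sex"].astype(str).str.lower()
    return df


def write_panel_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=PANEL_COLUMNS)


def _read_table(path, required, positive=()):
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise PanelValidationError(f"{path}: missing columns {missing}")
    for col in positive:
        bad = df[col] < 0
        if bad.any():
            raise PanelValidationError(
                f"{path}: negative {col} at lines {_lines(df, bad)}")
    return df


def read_counts_csv(path) -> pd.DataFrame:
    """Age-grouped mortality counts: age_start, age_width, population, deaths."""
    return _read_table(path, ["age_start", "age_width", "population", "deaths"],
                       positive=["population", "deaths"])


def write_counts_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_prevalence_csv(path) -> pd.DataFrame:
    """Age-grouped prevalence counts: age_start, age_width, n, cases."""
    df = _read_table(path, ["age_start", "age_width", "n", "cases"],
                     positive=["n", "cases"])
    bad = df["cases"] > df["n"]
    if bad.any():
        raise PanelValidationError(f"{path}: cases exceed n at lines {_lines(df, bad)}")
    return df


def write_prevalence_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def write_lifetable_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def write_hale_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
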