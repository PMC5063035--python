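"""Input-table schemas, validation and CSV I/O.

Four tables flow through the pipeline, mirroring the shape of claims
extracts:

* ``patients``   — patient_id, birth_date, sex ('M'/'F'), dialect
* ``med_events`` — one row per prescribed/dispensed pack-event:
  patient_id, date, drug_code, packs
* ``dx_events``  — diagnosis / long-term-condition / hospital-discharge
  events: patient_id, date, condition_code, source_kind
* ``truth``      — simulator-only planted ground truth per patient

Dates are ISO-8601 in files and ``datetime.date`` objects in memory; row
order on disk is deterministic (patient id, then date, then remaining
columns) so identical inputs give byte-identical files.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

PATIENT_COLUMNS = ["patient_id", "birth_date", "sex", "dialect"]
MED_EVENT_COLUMNS = ["patient_id", "date", "drug_code", "packs"]
DX_EVENT_COLUMNS = ["patient_id", "date", "condition_code", "source_kind"]
TRUTH_COLUMNS = [
    "patient_id",
    "should_be_included",
    "reason",
    "entry_date",
    "age_at_entry",
    "saba_overuse",
    "laba_no_ics",
    "laba_unbalanced",
]


class SchemaError(ValueError):
    """An input table violates its documented schema."""


def _require_columns(df: pd.DataFrame, columns: list[str], name: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{name} table is missing columns {missing}")


def validate_patients(df: pd.DataFrame) -> None:
    _require_columns(df, PATIENT_COLUMNS, "patients")
    if df["patient_id"].duplicated().any():
        dupes = df.loc[df["patient_id"].duplicated(), "patient_id"].tolist()
        raise SchemaError(f"duplicate patient ids: {dupes[:5]}")


def validate_med_events(df: pd.DataFrame) -> None:
    _require_columns(df, MED_EVENT_COLUMNS, "med_events")
    bad = df.index[pd.to_numeric(df["packs"], errors="coerce").fillna(-1) < 0]
    if len(bad):
        raise SchemaError(
            f"med_events rows with negative or non-numeric packs: {list(bad[:5])}"
        )


def validate_dx_events(df: pd.DataFrame) -> None:
    _require_columns(df, DX_EVENT_COLUMNS, "dx_events")


def _parse_dates(df: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    for col in columns:
        if col in df.columns:
            df[col] = pd.to_datetime(df[col], format="ISO8601").dt.date
    return df


def read_patients(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str})
    validate_patients(df)
    return _parse_dates(df, ["birth_date"])


def read_med_events(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str, "drug_code": str})
    validate_med_events(df)
    df["packs"] = df["packs"].astype(int)
    return _parse_dates(df, ["date"])


def read_dx_events(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str, "condition_code": str})
    validate_dx_events(df)
    return _parse_dates(df, ["date"])


def sort_for_output(df: pd.DataFrame) -> pd.DataFrame:
    """Deterministic row order: patient id, then date, then everything else."""
    keys = [c for c in df.columns if c in ("patient_id", "date")] + [
        c for c in df.columns if c not in ("patient_id", "date")
    ]
    if df.empty:
        return df
    return df.sort_values(keys, kind="mergesort").reset_index(drop=True)
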