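from __future__ import annotations

from datetime import date

import pandas as pd
import pytest

from asthmaclaims import Dialect, Terminology


@pytest.fixture(scope="session")
def terminology() -> Terminology:
    return Terminology.default()


@pytest.fixture(scope="session")
def code_of(terminology):
    """First terminology code of a drug class for a dialect."""

    def _code(drug_class, dialect=Dialect.DISPENSATION_FR_LIKE) -> str:
        return terminology.drug_codes_for(dialect, drug_class)[0]

    return _code


def make_patients(rows: list[dict]) -> pd.DataFrame:
    defaults = {"sex": "F", "dialect": Dialect.DISPENSATION_FR_LIKE.value}
    return pd.DataFrame([{**defaults, **r} for r in rows])


def make_med_events(rows: list[tuple[str, date, str, int]]) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=["patient_id", "date", "drug_code", "packs"])


def make_dx_events(rows: list[tuple[str, date, str, str]] | None = None) -> pd.DataFrame:
    return pd.DataFrame(
        rows or [], columns=["patient_id", "date", "condition_code", "source_kind"]
    )
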