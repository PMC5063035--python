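"""Cohort construction from longitudinal medication-event tables.

A patient qualifies for the cohort of a given calendar year when they have
respiratory-drug events (SABA, single LABA, single ICS, fixed-dose ICS/LABA
combination, LTRA or xanthine) on at least three distinct dates inside that
year; the third distinct date is the entry date.  The prescription dialect
additionally requires a coded asthma diagnosis on or before entry.  Patients
aged outside 6-40 completed years at entry are excluded, as are patients
with any of the following in the 12-month lookback window
``[entry - 12 months, entry)``:

* any omalizumab event;
* chronic oral-corticosteroid use — prescription dialect: at least five OCS
  prescription events on at least four distinct dates; dispensation dialect:
  OCS dispensations on at least four distinct dates spanning at least two
  civil calendar quarters;
* COPD, recorded either as a coded condition or as any tiotropium /
  indacaterol event with no ICS-containing event in the same window;
* cystic fibrosis, lung cancer, bronchiectasis, tuberculosis or sarcoidosis
  as coded conditions.

Patients whose data coverage ends before ``entry + 12 months`` are excluded
for insufficient follow-up.  Rules run in the fixed order above; the first
failure is the recorded exclusion reason.  Month arithmetic keeps the
day-of-month, clamped to month end, and the entry date itself belongs to
follow-up, never to lookback.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from enum import Enum
from typing import Iterable, Sequence

import pandas as pd
from pydantic import BaseModel, Field, field_validator

from ._calendar import add_months, completed_years, quarter_of
from ._rounding import round_half_up
from .tables import validate_dx_events, validate_med_events, validate_patients
from .terminology import (
    ConditionLabel,
    Dialect,
    DrugClass,
    ICS_CONTAINING_CLASSES,
    Terminology,
    is_respiratory,
)


class AgeGroup(str, Enum):
    CHILD_6_13 = "CHILD_6_13"
    ADULT_14_40 = "ADULT_14_40"


class Outcome(str, Enum):
    """Per-candidate selection outcome; order of members is evaluation order."""

    INCLUDED = "INCLUDED"
    NOT_ENOUGH_EVENTS = "NOT_ENOUGH_EVENTS"
    NO_ASTHMA_DIAGNOSIS = "NO_ASTHMA_DIAGNOSIS"
    AGE_OUT_OF_RANGE = "AGE_OUT_OF_RANGE"
    OMALIZUMAB = "OMALIZUMAB"
    CHRONIC_OCS = "CHRONIC_OCS"
    COPD_OR_COPD_DRUG = "COPD_OR_COPD_DRUG"
    CF = "CF"
    LUNG_CANCER = "LUNG_CANCER"
    BRONCHIECTASIS = "BRONCHIECTASIS"
    TB = "TB"
    SARCOIDOSIS = "SARCOIDOSIS"
    INSUFFICIENT_FOLLOWUP = "INSUFFICIENT_FOLLOWUP"


_CONDITION_OUTCOME = {
    ConditionLabel.CYSTIC_FIBROSIS: Outcome.CF,
    ConditionLabel.LUNG_CANCER: Outcome.LUNG_CANCER,
    ConditionLabel.BRONCHIECTASIS: Outcome.BRONCHIECTASIS,
    ConditionLabel.TUBERCULOSIS: Outcome.TB,
    ConditionLabel.SARCOIDOSIS: Outcome.SARCOIDOSIS,
}


class CohortConfig(BaseModel):
    """Country-year configuration of the selection algorithm.

    ``ocs_prescription_threshold`` is the minimum number of lookback OCS
    prescription events that marks chronic use in the prescription dialect;
    the default 5 reads "more than 4" strictly, 4 gives the inclusive
    reading.
    """

    dialect: Dialect
    cohort_year: int = Field(ge=1900, le=2100)
    data_end_date: date
    ocs_prescription_threshold: int = Field(default=5, ge=1)

    @field_validator("data_end_date", mode="before")
    @classmethod
    def _coerce_date(cls, v):
        if isinstance(v, str):
            return date.fromisoformat(v)
        return v


@dataclass(frozen=True)
class CohortMember:
    patient_id: str
    entry_date: date
    age_at_entry: int
    age_group: AgeGroup
    sex: str
    lookback_start: date  # lookback window is [lookback_start, entry_date)
    followup_end: date  # follow-up window is [entry_date, followup_end)


@dataclass(frozen=True)
class ExclusionReport:
    patient_id: str
    outcome: Outcome


@dataclass
class CohortResult:
    members: pd.DataFrame
    exclusions: pd.DataFrame
    baseline: pd.DataFrame


def find_entry_date(
    event_dates: Iterable[tuple[date, DrugClass]], year: int
) -> date | None:
    """Third distinct calendar date in ``year`` with a respiratory-drug event.

    Several respiratory events on one date count as a single date.  Returns
    None when fewer than three such distinct dates exist.
    """
    dates = sorted(
        {d for d, cls in event_dates if d.year == year and is_respiratory(cls)}
    )
    return dates[2] if len(dates) >= 3 else None


def chronic_ocs_flag(
    ocs_dates: Sequence[date], dialect: Dialect, prescription_threshold: int = 5
) -> bool:
    """Chronic oral-corticosteroid use over a 12-month lookback.

    ``ocs_dates`` holds the date of every OCS event inside the lookback
    window (one element per event, repeats allowed).  Prescription dialect:
    at least ``prescription_threshold`` events on >= 4 distinct dates.
    Dispensation dialect: >= 4 distinct dates spanning >= 2 civil quarters.
    """
    distinct = set(ocs_dates)
    if dialect is Dialect.PRESCRIPTION_UK_LIKE:
        return len(ocs_dates) >= prescription_threshold and len(distinct) >= 4
    quarters = {quarter_of(d) for d in distinct}
    return len(distinct) >= 4 and len(quarters) >= 2


def age_group_of(age: int) -> AgeGroup:
    return AgeGroup.CHILD_6_13 if age <= 13 else AgeGroup.ADULT_14_40


def apply_exclusions(
    *,
    patient_id: str,
    birth_date: date,
    entry_date: date,
    med_events: Sequence[tuple[date, DrugClass]],
    dx_events: Sequence[tuple[date, ConditionLabel]],
    config: CohortConfig,
) -> tuple[Outcome, int]:
    """Run the exclusion cascade for one candidate with a known entry date.

    Returns the first triggered outcome (INCLUDED when none trigger) and the
    age at entry in completed years.  ``med_events``/``dx_events`` are the
    patient's full event lists; windowing happens here.
    """
    if entry_date is None:  # pragma: no cover - contract
        raise ValueError("apply_exclusions requires an entry date")
    age = completed_years(birth_date, entry_date)
    lookback_start = add_months(entry_date, -12)

    def in_lookback(d: date) -> bool:
        return lookback_start <= d < entry_date

    if not 6 <= age <= 40:
        return Outcome.AGE_OUT_OF_RANGE, age

    classes_lb = [(d, c) for d, c in med_events if in_lookback(d)]
    if any(c is DrugClass.OMALIZUMAB for _, c in classes_lb):
        return Outcome.OMALIZUMAB, age

    ocs_dates = [d for d, c in classes_lb if c is DrugClass.OCS]
    if chronic_ocs_flag(ocs_dates, config.dialect, config.ocs_prescription_threshold):
        return Outcome.CHRONIC_OCS, age

    copd_coded = any(
        lbl is ConditionLabel.COPD for d, lbl in dx_events if in_lookback(d)
    )
    copd_drug = any(
        c in (DrugClass.TIOTROPIUM, DrugClass.INDACATEROL) for _, c in classes_lb
    ) and not any(c in ICS_CONTAINING_CLASSES for _, c in classes_lb)
    if copd_coded or copd_drug:
        return Outcome.COPD_OR_COPD_DRUG, age

    lb_conditions = {lbl for d, lbl in dx_events if in_lookback(d)}
    for label in (
        ConditionLabel.CYSTIC_FIBROSIS,
        ConditionLabel.LUNG_CANCER,
        ConditionLabel.BRONCHIECTASIS,
        ConditionLabel.TUBERCULOSIS,
        ConditionLabel.SARCOIDOSIS,
    ):
        if label in lb_conditions:
            return _CONDITION_OUTCOME[label], age

    if config.data_end_date < add_months(entry_date, 12):
        return Outcome.INSUFFICIENT_FOLLOWUP, age

    return Outcome.INCLUDED, age


def baseline_table(members: pd.DataFrame) -> pd.DataFrame:
    """Baseline description of a cohort: N, mean age (s.d.), strata counts.

    Mirrors the usual claims-cohort baseline layout: total N, mean age with
    sample (n-1) standard deviation, then counts and half-up 1-decimal
    percentages for children (6-13), adults (14-40) and males.  An empty
    cohort yields zero counts and missing mean/s.d./percentages.
    """
    n = len(members)
    rows: list[tuple[str, object]] = [("n", n)]
    if n == 0:
        rows += [
            ("mean_age", None),
            ("sd_age", None),
            ("children_n", 0),
            ("children_pct", None),
            ("adults_n", 0),
            ("adults_pct", None),
            ("males_n", 0),
            ("males_pct", None),
        ]
        return pd.DataFrame(rows, columns=["statistic", "value"])
    ages = members["age_at_entry"].astype(float)
    children = int((members["age_group"] == AgeGroup.CHILD_6_13.value).sum())
    males = int((members["sex"] == "M").sum())
    rows += [
        ("mean_age", float(ages.mean())),
        ("sd_age", float(ages.std(ddof=1)) if n > 1 else None),
        ("children_n", children),
        ("children_pct", round_half_up(100.0 * children / n, 1)),
        ("adults_n", n - children),
        ("adults_pct", round_half_up(100.0 * (n - children) / n, 1)),
        ("males_n", males),
        ("males_pct", round_half_up(100.0 * males / n, 1)),
    ]
    return pd.DataFrame(rows, columns=["statistic", "value"])


def build_cohort(
    patients: pd.DataFrame,
    med_events: pd.DataFrame,
    dx_events: pd.DataFrame,
    config: CohortConfig,
    terminology: Terminology | None = None,
) -> CohortResult:
    """Apply the full selection algorithm to raw event tables.

    Every patient in ``patients`` receives exactly one outcome; included
    patients appear in ``members`` with their entry date, age group and
    analysis windows, all others in ``exclusions`` with the first triggered
    reason.  Input row order never influences any outcome.
    """
    terminology = terminology or Terminology.default()
    validate_patients(patients)
    validate_med_events(med_events)
    validate_dx_events(dx_events)

    med = med_events.copy()
    med["drug_class"] = [terminology.classify_drug(c) for c in med["drug_code"]]
    dx = dx_events.copy()
    dx["condition"] = [terminology.classify_condition(c) for c in dx["condition_code"]]

    med_by_pid: dict[str, list[tuple[date, DrugClass]]] = {
        pid: list(zip(g["date"], g["drug_class"]))
        for pid, g in med.groupby("patient_id", sort=True)
    }
    dx_by_pid: dict[str, list[tuple[date, ConditionLabel]]] = {
        pid: list(zip(g["date"], g["condition"]))
        for pid, g in dx.groupby("patient_id", sort=True)
    }

    member_rows: list[dict] = []
    exclusion_rows: list[dict] = []
    for row in patients.sort_values("patient_id").itertuples(index=False):
        pid = row.patient_id
        p_med = med_by_pid.get(pid, [])
        p_dx = dx_by_pid.get(pid, [])
        entry = find_entry_date(p_med, config.cohort_year)
        if entry is None:
            exclusion_rows.append(
                {"patient_id": pid, "outcome": Outcome.NOT_ENOUGH_EVENTS.value}
            )
            continue
        if config.dialect is Dialect.PRESCRIPTION_UK_LIKE and not any(
            lbl is ConditionLabel.ASTHMA and d <= entry for d, lbl in p_dx
        ):
            exclusion_rows.append(
                {"patient_id": pid, "outcome": Outcome.NO_ASTHMA_DIAGNOSIS.value}
            )
            continue
        outcome, age = apply_exclusions(
            patient_id=pid,
            birth_date=row.birth_date,
            entry_date=entry,
            med_events=p_med,
            dx_events=p_dx,
            config=config,
        )
        if outcome is not Outcome.INCLUDED:
            exclusion_rows.append({"patient_id": pid, "outcome": outcome.value})
            continue
        member_rows.append(
            {
                "patient_id": pid,
                "entry_date": entry,
                "age_at_entry": age,
                "age_group": age_group_of(age).value,
                "sex": row.sex,
                "lookback_start": add_months(entry, -12),
                "followup_end": add_months(entry, 12),
            }
        )

    members = pd.DataFrame(
        member_rows,
        columns=[
            "patient_id",
            "entry_date",
            "age_at_entry",
            "age_group",
            "sex",
            "lookback_start",
            "followup_end",
        ],
    )
    exclusions = pd.DataFrame(exclusion_rows, columns=["patient_id", "outcome"])
    return CohortResult(members, exclusions, baseline_table(members))
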