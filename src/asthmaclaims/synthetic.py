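"""Synthetic two-dialect claims generator with planted ground truth.

The generator emulates the structure of the two claims sources the pipeline
is designed for — a prescription-style primary-care extract with coded
diagnoses, and a dispensation-style reimbursement extract with long-term-
condition flags instead of diagnoses — and plants every inclusion,
exclusion and inappropriate-use pattern *constructively*: events are written
so that each patient satisfies or violates the selection and pattern rules
by construction, and the planted truth is recorded per patient.  Downstream
tests can therefore check the cohort builder exactly (patient by patient)
rather than statistically, while planted pattern prevalences remain
Bernoulli draws so that measured prevalences admit binomial checks.

All randomness comes from a single numpy Generator consumed in a fixed,
documented per-patient order, so one seed + config gives byte-identical
output tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

from ._calendar import add_months
from .cohort import Outcome
from .tables import (
    DX_EVENT_COLUMNS,
    MED_EVENT_COLUMNS,
    PATIENT_COLUMNS,
    TRUTH_COLUMNS,
    sort_for_output,
)
from .terminology import ConditionLabel, Dialect, DrugClass, SourceKind, Terminology

#: Exclusion channels drawable per patient, in the order probability mass is
#: assigned.  Keys of ``SimulationConfig.exclusion_rates``.
EXCLUSION_CHANNELS = (
    "not_enough_events",
    "no_asthma_diagnosis",
    "omalizumab",
    "chronic_ocs",
    "copd_diagnosis",
    "copd_drug",
    "cystic_fibrosis",
    "lung_cancer",
    "bronchiectasis",
    "tuberculosis",
    "sarcoidosis",
    "insufficient_followup",
)

_CHANNEL_OUTCOME = {
    "not_enough_events": Outcome.NOT_ENOUGH_EVENTS,
    "no_asthma_diagnosis": Outcome.NO_ASTHMA_DIAGNOSIS,
    "omalizumab": Outcome.OMALIZUMAB,
    "chronic_ocs": Outcome.CHRONIC_OCS,
    "copd_diagnosis": Outcome.COPD_OR_COPD_DRUG,
    "copd_drug": Outcome.COPD_OR_COPD_DRUG,
    "cystic_fibrosis": Outcome.CF,
    "lung_cancer": Outcome.LUNG_CANCER,
    "bronchiectasis": Outcome.BRONCHIECTASIS,
    "tuberculosis": Outcome.TB,
    "sarcoidosis": Outcome.SARCOIDOSIS,
    "insufficient_followup": Outcome.INSUFFICIENT_FOLLOWUP,
}

_CHANNEL_CONDITION = {
    "copd_diagnosis": ConditionLabel.COPD,
    "cystic_fibrosis": ConditionLabel.CYSTIC_FIBROSIS,
    "lung_cancer": ConditionLabel.LUNG_CANCER,
    "bronchiectasis": ConditionLabel.BRONCHIECTASIS,
    "tuberculosis": ConditionLabel.TUBERCULOSIS,
    "sarcoidosis": ConditionLabel.SARCOIDOSIS,
}


def default_age_weights() -> dict[int, float]:
    """Age mix at cohort-year start: mostly 6-40 with a small out-of-band tail.

    Roughly 30% of in-band mass on ages 6-13 and 70% on 14-40, echoing the
    child/adult split seen in primary-care asthma cohorts, plus ~6% of
    patients just outside the eligible band to exercise age exclusions.
    """
    weights: dict[int, float] = {}
    for age in range(3, 6):
        weights[age] = 0.03 / 3
    for age in range(6, 14):
        weights[age] = 0.28 / 8
    for age in range(14, 41):
        weights[age] = 0.63 / 27
    for age in range(41, 46):
        weights[age] = 0.03 / 5
    return weights


def default_exclusion_rates(dialect: Dialect) -> dict[str, float]:
    rates = {
        "not_enough_events": 0.05,
        "omalizumab": 0.01,
        "chronic_ocs": 0.01,
        "copd_diagnosis": 0.01,
        "copd_drug": 0.01,
        "cystic_fibrosis": 0.005,
        "lung_cancer": 0.005,
        "bronchiectasis": 0.005,
        "tuberculosis": 0.005,
        "sarcoidosis": 0.005,
        "insufficient_followup": 0.02,
    }
    if dialect is Dialect.PRESCRIPTION_UK_LIKE:
        rates["no_asthma_diagnosis"] = 0.01
    return rates


class PlantedPrevalence(BaseModel):
    """Bernoulli probabilities of each pattern among eligible patients."""

    saba_overuse: float = Field(default=0.10, ge=0.0, le=1.0)
    laba_no_ics: float = Field(default=0.02, ge=0.0, le=1.0)
    laba_unbalanced: float = Field(default=0.02, ge=0.0, le=1.0)

    @model_validator(mode="after")
    def _laba_patterns_exclusive(self):
        if self.laba_no_ics + self.laba_unbalanced > 1.0 + 1e-12:
            raise ValueError(
                "laba_no_ics and laba_unbalanced are mutually exclusive "
                "assignments; their probabilities must sum to <= 1"
            )
        return self


class SimulationConfig(BaseModel):
    seed: int = Field(ge=0, lt=2**31)
    n_patients: int = Field(ge=0)
    dialect: Dialect
    cohort_year: int = Field(default=2013, ge=1900, le=2100)
    age_weights: dict[int, float] | None = None
    sex_ratio_male: float = Field(default=0.52, ge=0.0, le=1.0)
    planted_prevalence: PlantedPrevalence = Field(default_factory=PlantedPrevalence)
    exclusion_rates: dict[str, float] | None = None
    events_per_patient_year: float = Field(default=6.0, gt=0.0)
    pack_weights: dict[int, float] = Field(default_factory=lambda: {1: 0.7, 2: 0.2, 3: 0.1})
    data_end_date: date | None = None

    @model_validator(mode="after")
    def _fill_and_check(self):
        if self.age_weights is None:
            self.age_weights = default_age_weights()
        if any(not 0 <= a <= 60 for a in self.age_weights):
            raise ValueError("age_weights keys must be integer ages 0-60")
        if any(w < 0 for w in self.age_weights.values()) or sum(self.age_weights.values()) <= 0:
            raise ValueError("age_weights must be non-negative with positive sum")
        if self.exclusion_rates is None:
            self.exclusion_rates = default_exclusion_rates(self.dialect)
        unknown = set(self.exclusion_rates) - set(EXCLUSION_CHANNELS)
        if unknown:
            raise ValueError(f"unknown exclusion channels: {sorted(unknown)}")
        if any(not 0.0 <= r <= 1.0 for r in self.exclusion_rates.values()):
            raise ValueError("exclusion rates must lie in [0, 1]")
        if sum(self.exclusion_rates.values()) > 1.0 + 1e-12:
            raise ValueError("exclusion rates must sum to <= 1")
        if (
            self.dialect is Dialect.DISPENSATION_FR_LIKE
            and self.exclusion_rates.get("no_asthma_diagnosis", 0.0) > 0
        ):
            raise ValueError(
                "no_asthma_diagnosis channel is undefined for the dispensation "
                "dialect (it records no diagnoses)"
            )
        if any(k < 1 for k in self.pack_weights) or sum(self.pack_weights.values()) <= 0:
            raise ValueError("pack_weights must map positive pack sizes to positive mass")
        if self.data_end_date is None:
            self.data_end_date = date(self.cohort_year + 1, 10, 31)
        latest_entry = min(
            date(self.cohort_year, 12, 31), add_months(self.data_end_date, -12)
        )
        if latest_entry < date(self.cohort_year, 3, 1):
            raise ValueError(
                "data_end_date leaves no room for entries with 12 months of "
                "follow-up (needs coverage through at least 1 March of the "
                "following year)"
            )
        if (
            self.exclusion_rates.get("insufficient_followup", 0.0) > 0
            and latest_entry >= date(self.cohort_year, 12, 31)
        ):
            raise ValueError(
                "insufficient_followup cannot be planted: every entry date in "
                "the cohort year already has 12 months of data coverage"
            )
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls.model_validate(raw)


@dataclass
class SyntheticTables:
    patients: pd.DataFrame
    med_events: pd.DataFrame
    dx_events: pd.DataFrame
    truth: pd.DataFrame


class _Builder:
    """Accumulates event rows for one simulation run."""

    def __init__(self, config: SimulationConfig, terminology: Terminology):
        self.cfg = config
        self.term = terminology
        self.rng = np.random.default_rng(config.seed)
        self.patients: list[dict] = []
        self.med: list[dict] = []
        self.dx: list[dict] = []
        self.truth: list[dict] = []
        self.ages = np.array(sorted(config.age_weights))
        probs = np.array([config.age_weights[a] for a in self.ages], dtype=float)
        self.age_probs = probs / probs.sum()
        self.pack_sizes = np.array(sorted(config.pack_weights))
        pw = np.array([config.pack_weights[s] for s in self.pack_sizes], dtype=float)
        self.pack_probs = pw / pw.sum()
        self.jan1 = date(config.cohort_year, 1, 1)
        self.dec31 = date(config.cohort_year, 12, 31)
        self.latest_entry = min(self.dec31, add_months(config.data_end_date, -12))

    # -- small draw helpers (consumed in documented order) ----------------

    def _pick_code(self, drug_class: DrugClass) -> str:
        codes = self.term.drug_codes_for(self.cfg.dialect, drug_class)
        if not codes:
            raise ValueError(f"terminology has no {drug_class} codes for {self.cfg.dialect}")
        return codes[int(self.rng.integers(len(codes)))]

    def _pick_condition_code(self, label: ConditionLabel) -> str:
        codes = self.term.condition_codes_for(self.cfg.dialect, label)
        if not codes:
            raise ValueError(f"terminology has no {label} codes for {self.cfg.dialect}")
        return codes[int(self.rng.integers(len(codes)))]

    def _pack_run(self, target: int) -> list[int]:
        """Pack sizes drawn from the configured mix, trimmed to sum to target."""
        out: list[int] = []
        remaining = target
        while remaining > 0:
            p = int(self.pack_sizes[int(self.rng.choice(len(self.pack_sizes), p=self.pack_probs))])
            p = min(p, remaining)
            out.append(p)
            remaining -= p
        return out

    def _med(self, pid: str, d: date, drug_class: DrugClass, packs: int = 1) -> None:
        self.med.append(
            {"patient_id": pid, "date": d, "drug_code": self._pick_code(drug_class), "packs": packs}
        )

    def _dx(self, pid: str, d: date, label: ConditionLabel, source: SourceKind) -> None:
        self.dx.append(
            {
                "patient_id": pid,
                "date": d,
                "condition_code": self._pick_condition_code(label),
                "source_kind": source.value,
            }
        )

    def _dx_source(self) -> SourceKind:
        if self.cfg.dialect is Dialect.PRESCRIPTION_UK_LIKE:
            return SourceKind.DIAGNOSIS
        return (
            SourceKind.LTC_FLAG
            if self.rng.random() < 0.7
            else SourceKind.HOSPITAL_DISCHARGE
        )

    # -- per-patient generation -------------------------------------------

    def add_patient(self, idx: int) -> None:
        cfg = self.cfg
        rng = self.rng
        pid = f"P{idx:06d}"
        sex = "M" if rng.random() < cfg.sex_ratio_male else "F"
        age = int(self.ages[int(rng.choice(len(self.ages), p=self.age_probs))])
        birth = date(cfg.cohort_year - age, 1, 1)
        self.patients.append(
            {"patient_id": pid, "birth_date": birth, "sex": sex, "dialect": cfg.dialect.value}
        )

        if not 6 <= age <= 40:
            channel = "age_out_of_range"
        else:
            u = rng.random()
            channel = "eligible"
            cum = 0.0
            for name in EXCLUSION_CHANNELS:
                cum += cfg.exclusion_rates.get(name, 0.0)
                if u < cum:
                    channel = name
                    break

        patterns = {k: False for k in ("saba_overuse", "laba_no_ics", "laba_unbalanced")}
        if channel == "eligible":
            patterns["saba_overuse"] = rng.random() < cfg.planted_prevalence.saba_overuse
            v = rng.random()
            if v < cfg.planted_prevalence.laba_no_ics:
                patterns["laba_no_ics"] = True
            elif v < cfg.planted_prevalence.laba_no_ics + cfg.planted_prevalence.laba_unbalanced:
                patterns["laba_unbalanced"] = True

        if channel == "not_enough_events":
            # two distinct respiratory dates only: never reaches an entry date
            offs = np.sort(rng.choice(300, size=2, replace=False))
            d1 = self.jan1 + timedelta(days=int(offs[0]))
            d2 = self.jan1 + timedelta(days=int(offs[1]))
            self._med(pid, d1, DrugClass.SABA)
            self._med(pid, d2, DrugClass.SABA)
            if rng.random() < 0.5:  # second event on an already-used date
                self._med(pid, d2, DrugClass.ICS_MONO)
            if cfg.dialect is Dialect.PRESCRIPTION_UK_LIKE:
                self._dx(pid, d1, ConditionLabel.ASTHMA, SourceKind.DIAGNOSIS)
            self.truth.append(self._truth_row(pid, channel, None, age, patterns))
            return

        # entry date: uniform over the valid range for the channel
        if channel == "insufficient_followup":
            lo = self.latest_entry + timedelta(days=1)
            hi = self.dec31
        else:
            lo = date(cfg.cohort_year, 3, 1)
            hi = self.latest_entry
        span = (hi - lo).days + 1
        entry = lo + timedelta(days=int(rng.integers(span)))

        # two strictly earlier qualifying dates
        offs = np.sort(rng.choice((entry - self.jan1).days, size=2, replace=False))
        d1 = self.jan1 + timedelta(days=int(offs[0]))
        d2 = self.jan1 + timedelta(days=int(offs[1]))
        if channel == "copd_drug":
            lookback_classes = [DrugClass.SABA, DrugClass.LTRA, DrugClass.XANTHINE]
        else:
            lookback_classes = [
                DrugClass.SABA,
                DrugClass.ICS_MONO,
                DrugClass.FDC_ICS_LABA,
                DrugClass.LTRA,
            ]
        for d in (d1, d2):
            cls = lookback_classes[int(rng.integers(len(lookback_classes)))]
            self._med(pid, d, cls)

        if cfg.dialect is Dialect.PRESCRIPTION_UK_LIKE and channel != "no_asthma_diagnosis":
            self._dx(pid, d1, ConditionLabel.ASTHMA, SourceKind.DIAGNOSIS)

        self._plant_exclusion_trigger(pid, entry, channel)
        self._emit_followup(pid, entry, patterns)
        planted_entry = entry
        self.truth.append(self._truth_row(pid, channel, planted_entry, age, patterns))

    def _plant_exclusion_trigger(self, pid: str, entry: date, channel: str) -> None:
        rng = self.rng
        if channel == "omalizumab":
            self._med(pid, entry - timedelta(days=int(rng.integers(1, 331))), DrugClass.OMALIZUMAB)
        elif channel == "chronic_ocs":
            ocs_dates = [add_months(entry, -m) for m in (10, 7, 4, 1)]
            for d in ocs_dates:
                self._med(pid, d, DrugClass.OCS)
            if self.cfg.dialect is Dialect.PRESCRIPTION_UK_LIKE:
                self._med(pid, ocs_dates[0], DrugClass.OCS)  # 5th prescription event
        elif channel == "copd_drug":
            cls = DrugClass.TIOTROPIUM if rng.random() < 0.5 else DrugClass.INDACATEROL
            self._med(pid, entry - timedelta(days=int(rng.integers(1, 331))), cls)
        elif channel in _CHANNEL_CONDITION:
            self._dx(
                pid,
                entry - timedelta(days=int(rng.integers(1, 331))),
                _CHANNEL_CONDITION[channel],
                self._dx_source(),
            )

    def _emit_followup(self, pid: str, entry: date, patterns: dict[str, bool]) -> None:
        """Write follow-up pack-events realising exactly the planted patterns."""
        cfg = self.cfg
        rng = self.rng
        fu_limit = min(add_months(entry, 12), cfg.data_end_date + timedelta(days=1))
        fu_days = (fu_limit - entry).days

        if patterns["saba_overuse"]:
            saba_target = 12 + int(rng.poisson(3.0))
        else:
            # 1..8 packs: at least one reliever event anchors the entry date,
            # while staying safely under the overuse threshold
            saba_target = 1 + min(7, int(rng.poisson(cfg.events_per_patient_year / 2.0)))
        if patterns["laba_no_ics"]:
            laba_target = 1 + int(rng.integers(4))
            ics_target = fdc_target = 0
        elif patterns["laba_unbalanced"]:
            ics_target = 1 + int(rng.integers(2))
            laba_target = 2 * ics_target + int(rng.integers(3))
            fdc_target = int(rng.integers(2))
        else:
            laba_target = 0
            ics_target = min(4, int(rng.poisson(cfg.events_per_patient_year / 6.0)))
            fdc_target = min(4, int(rng.poisson(cfg.events_per_patient_year / 6.0)))
        ltra_target = int(rng.integers(3))
        xan_target = int(rng.integers(2))

        events: list[tuple[DrugClass, int]] = []
        for drug_class, target in (
            (DrugClass.SABA, saba_target),
            (DrugClass.LABA_MONO, laba_target),
            (DrugClass.ICS_MONO, ics_target),
            (DrugClass.FDC_ICS_LABA, fdc_target),
            (DrugClass.LTRA, ltra_target),
            (DrugClass.XANTHINE, xan_target),
        ):
            for packs in self._pack_run(target):
                events.append((drug_class, packs))

        for i, (drug_class, packs) in enumerate(events):
            if i == 0:
                d = entry  # the third qualifying date is itself exposure
            else:
                d = entry + timedelta(days=int(rng.integers(fu_days)))
            self._med(pid, d, drug_class, packs)

    @staticmethod
    def _truth_row(
        pid: str, channel: str, entry: date | None, age: int, patterns: dict[str, bool]
    ) -> dict:
        if channel == "eligible":
            reason = Outcome.INCLUDED
        elif channel == "age_out_of_range":
            reason = Outcome.AGE_OUT_OF_RANGE
        else:
            reason = _CHANNEL_OUTCOME[channel]
        return {
            "patient_id": pid,
            "should_be_included": reason is Outcome.INCLUDED,
            "reason": reason.value,
            "entry_date": entry,
            "age_at_entry": age,
            "saba_overuse": patterns["saba_overuse"],
            "laba_no_ics": patterns["laba_no_ics"],
            "laba_unbalanced": patterns["laba_unbalanced"],
        }


def generate(
    config: SimulationConfig, terminology: Terminology | None = None
) -> SyntheticTables:
    """Generate one synthetic claims database with planted ground truth."""
    terminology = terminology or Terminology.default()
    builder = _Builder(config, terminology)
    for idx in range(config.n_patients):
        builder.add_patient(idx)
    patients = sort_for_output(pd.DataFrame(builder.patients, columns=PATIENT_COLUMNS))
    med_events = sort_for_output(pd.DataFrame(builder.med, columns=MED_EVENT_COLUMNS))
    dx_events = sort_for_output(pd.DataFrame(builder.dx, columns=DX_EVENT_COLUMNS))
    # patient_id is unique in truth; entry_date may hold None, so sort on id only
    truth = (
        pd.DataFrame(builder.truth, columns=TRUTH_COLUMNS)
        .sort_values("patient_id")
        .reset_index(drop=True)
    )
    return SyntheticTables(patients, med_events, dx_events, truth)


def write_tables(tables: SyntheticTables, directory: str | Path) -> dict[str, Path]:
    """Write the four tables as CSV; deterministic order, ISO-8601 dates."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in (
        ("patients", tables.patients),
        ("med_events", tables.med_events),
        ("dx_events", tables.dx_events),
        ("truth", tables.truth),
    ):
        path = directory / f"{name}.csv"
        df.to_csv(path, index=False)
        paths[name] = path
    return paths


def read_tables(directory: str | Path) -> SyntheticTables:
    """Read back tables written by :func:`write_tables`."""
    from .tables import read_dx_events, read_med_events, read_patients

    directory = Path(directory)
    truth = pd.read_csv(directory / "truth.csv", dtype={"patient_id": str})
    if len(truth):
        truth["entry_date"] = pd.to_datetime(truth["entry_date"], format="ISO8601").dt.date
        truth.loc[truth["entry_date"].isna(), "entry_date"] = None
    return SyntheticTables(
        patients=read_patients(directory / "patients.csv"),
        med_events=read_med_events(directory / "med_events.csv"),
        dx_events=read_dx_events(directory / "dx_events.csv"),
        truth=truth,
    )
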