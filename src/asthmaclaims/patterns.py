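"""Inappropriate-therapy pattern flags over the 12-month follow-up window.

Treatment units are prescribed/dispensed packs.  Per cohort member, packs
are summed by therapeutic class over ``[entry, entry + 12 months)`` and
three flags are derived:

* SABA overuse — 12 or more reliever packs;
* LABA without ICS — any single-agent LABA pack with zero ICS packs of any
  form (single-agent or fixed-dose combination);
* unbalanced LABA/ICS — at least one single-agent ICS pack and at least
  twice as many single-agent LABA packs as single-agent ICS packs.

Fixed-dose combination packs never count as LABA exposure: the combination
guarantees ICS co-therapy, which is exactly what the two LABA patterns
screen for.  The two LABA flags are mutually exclusive by construction: the
zero-single-ICS case belongs to "LABA without ICS" when the patient also has
no combination packs, and to neither pattern when combination packs exist
(the ratio is undefined and ICS co-therapy is present).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from typing import Sequence

import pandas as pd

from ._calendar import add_months
from ._rounding import round_half_up
from .cohort import AgeGroup
from .tables import SchemaError, validate_med_events
from .terminology import DrugClass, Terminology

PATTERNS = ("saba_overuse", "laba_no_ics", "laba_unbalanced")

#: Minimum follow-up reliever packs that defines overuse.
SABA_OVERUSE_THRESHOLD = 12

#: Minimum single-LABA : single-ICS pack ratio that defines unbalanced use.
LABA_ICS_RATIO_THRESHOLD = 2


@dataclass(frozen=True)
class UnitCounts:
    """Follow-up pack counts by therapeutic class for one cohort member."""

    saba: int = 0
    laba_mono: int = 0
    ics_mono: int = 0
    fdc: int = 0
    ltra: int = 0
    xanthine: int = 0


@dataclass(frozen=True)
class PatternFlags:
    saba_overuse: bool
    laba_no_ics: bool
    laba_unbalanced: bool


_CLASS_FIELD = {
    DrugClass.SABA: "saba",
    DrugClass.LABA_MONO: "laba_mono",
    DrugClass.ICS_MONO: "ics_mono",
    DrugClass.FDC_ICS_LABA: "fdc",
    DrugClass.LTRA: "ltra",
    DrugClass.XANTHINE: "xanthine",
}


def count_units(
    entry_date: date,
    events: Sequence[tuple[date, DrugClass, int]],
    followup_end: date | None = None,
) -> UnitCounts:
    """Sum packs by class over the half-open follow-up window.

    ``events`` holds (date, drug class, packs) triples for one patient;
    events dated outside ``[entry_date, followup_end)`` or of a class with
    no pattern role (OCS, exclusion drugs, OTHER) contribute nothing.
    """
    end = followup_end or add_months(entry_date, 12)
    totals = dict.fromkeys(_CLASS_FIELD.values(), 0)
    for d, cls, packs in events:
        if packs < 0:
            raise SchemaError(f"negative pack count {packs} on {d}")
        field = _CLASS_FIELD.get(cls)
        if field is not None and entry_date <= d < end:
            totals[field] += int(packs)
    return UnitCounts(**totals)


def flag_saba_overuse(counts: UnitCounts) -> bool:
    return counts.saba >= SABA_OVERUSE_THRESHOLD


def flag_laba_no_ics(counts: UnitCounts) -> bool:
    return counts.laba_mono >= 1 and counts.ics_mono + counts.fdc == 0


def flag_laba_unbalanced(counts: UnitCounts) -> bool:
    return (
        counts.ics_mono >= 1
        and counts.laba_mono >= LABA_ICS_RATIO_THRESHOLD * counts.ics_mono
    )


def flags_from_counts(counts: UnitCounts) -> PatternFlags:
    return PatternFlags(
        saba_overuse=flag_saba_overuse(counts),
        laba_no_ics=flag_laba_no_ics(counts),
        laba_unbalanced=flag_laba_unbalanced(counts),
    )


def classify_cohort(
    members: pd.DataFrame,
    med_events: pd.DataFrame,
    terminology: Terminology | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-member unit counts and flags, plus stratified prevalence summary.

    Returns ``(flags, prevalence)``.  ``flags`` has one row per cohort
    member with their six class counts and three boolean flags.
    ``prevalence`` reports, per age stratum (children 6-13, adults 14-40,
    and ALL) and pattern: cohort N, number flagged, and the percentage
    rounded half-up to one decimal.
    """
    terminology = terminology or Terminology.default()
    validate_med_events(med_events)
    med = med_events.copy()
    med["drug_class"] = [terminology.classify_drug(c) for c in med["drug_code"]]
    by_pid = {
        pid: list(zip(g["date"], g["drug_class"], g["packs"]))
        for pid, g in med.groupby("patient_id", sort=True)
    }

    rows = []
    for m in members.sort_values("patient_id").itertuples(index=False):
        counts = count_units(m.entry_date, by_pid.get(m.patient_id, []), m.followup_end)
        flags = flags_from_counts(counts)
        rows.append(
            {
                "patient_id": m.patient_id,
                "age_group": m.age_group,
                "saba_units": counts.saba,
                "laba_mono_units": counts.laba_mono,
                "ics_mono_units": counts.ics_mono,
                "fdc_units": counts.fdc,
                "ltra_units": counts.ltra,
                "xanthine_units": counts.xanthine,
                "saba_overuse": flags.saba_overuse,
                "laba_no_ics": flags.laba_no_ics,
                "laba_unbalanced": flags.laba_unbalanced,
            }
        )
    flags_df = pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "age_group",
            "saba_units",
            "laba_mono_units",
            "ics_mono_units",
            "fdc_units",
            "ltra_units",
            "xanthine_units",
            "saba_overuse",
            "laba_no_ics",
            "laba_unbalanced",
        ],
    )

    strata = [g.value for g in AgeGroup] + ["ALL"]
    prev_rows = []
    for stratum in strata:
        sub = flags_df if stratum == "ALL" else flags_df[flags_df["age_group"] == stratum]
        n = len(sub)
        for pattern in PATTERNS:
            flagged = int(sub[pattern].sum()) if n else 0
            prev_rows.append(
                {
                    "stratum": stratum,
                    "pattern": pattern,
                    "n": n,
                    "n_flagged": flagged,
                    "percent": round_half_up(100.0 * flagged / n, 1) if n else None,
                }
            )
    prevalence = pd.DataFrame(
        prev_rows, columns=["stratum", "pattern", "n", "n_flagged", "percent"]
    )
    return flags_df, prevalence
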