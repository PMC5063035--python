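"""Selection algorithm: entry dates, exclusion cascade, baseline table.

Includes the small-instance oracle check: on randomly generated
micro-databases, the cohort builder must agree patient-for-patient with a
naive enumerator built on an independent calendar implementation.
"""

from __future__ import annotations

from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest

from asthmaclaims import (
    CohortConfig,
    Dialect,
    DrugClass,
    Outcome,
    baseline_table,
    build_cohort,
    chronic_ocs_flag,
    find_entry_date,
)
from asthmaclaims._calendar import add_months, completed_years

from _oracles import naive_outcome
from conftest import make_dx_events, make_med_events, make_patients

FR = Dialect.DISPENSATION_FR_LIKE
UK = Dialect.PRESCRIPTION_UK_LIKE


def fr_config(**kw):
    defaults = dict(dialect=FR, cohort_year=2013, data_end_date=date(2014, 12, 31))
    defaults.update(kw)
    return CohortConfig(**defaults)


# --- calendar conventions -------------------------------------------------


@pytest.mark.parametrize(
    "start,months,expected",
    [
        (date(2013, 1, 31), 1, date(2013, 2, 28)),  # clamped to month end
        (date(2012, 2, 29), 12, date(2013, 2, 28)),
        (date(2013, 5, 15), 12, date(2014, 5, 15)),
        (date(2013, 3, 31), -1, date(2013, 2, 28)),
    ],
)
def test_month_arithmetic_clamps_to_month_end(start, months, expected):
    assert add_months(start, months) == expected


def test_completed_years_turns_on_birthday():
    birth = date(2000, 6, 15)
    assert completed_years(birth, date(2013, 6, 14)) == 12
    assert completed_years(birth, date(2013, 6, 15)) == 13


# --- find_entry_date ------------------------------------------------------


def test_entry_is_third_distinct_respiratory_date():
    events = [
        (date(2013, 1, 5), DrugClass.SABA),
        (date(2013, 1, 5), DrugClass.ICS_MONO),  # same date counts once
        (date(2013, 3, 2), DrugClass.LTRA),
        (date(2013, 6, 9), DrugClass.SABA),
    ]
    assert find_entry_date(events, 2013) == date(2013, 6, 9)


def test_two_distinct_dates_yield_no_entry():
    events = [
        (date(2013, 1, 5), DrugClass.SABA),
        (date(2013, 1, 5), DrugClass.SABA),
        (date(2013, 3, 2), DrugClass.SABA),
    ]
    assert find_entry_date(events, 2013) is None


def test_non_qualifying_classes_never_anchor_entry():
    events = [
        (date(2013, 1, 5), DrugClass.OCS),
        (date(2013, 3, 2), DrugClass.OCS),
        (date(2013, 6, 9), DrugClass.OCS),
    ]
    assert find_entry_date(events, 2013) is None


def test_events_outside_cohort_year_ignored():
    events = [
        (date(2012, 12, 31), DrugClass.SABA),
        (date(2013, 1, 5), DrugClass.SABA),
        (date(2013, 3, 2), DrugClass.SABA),
        (date(2013, 6, 9), DrugClass.SABA),
    ]
    assert find_entry_date(events, 2013) == date(2013, 6, 9)


# --- chronic OCS ----------------------------------------------------------


def _dates(*days: int) -> list[date]:
    return [date(2013, 1, 1) + timedelta(days=d) for d in days]


def test_chronic_ocs_prescription_needs_five_events_on_four_dates():
    four_dates = _dates(0, 40, 80, 120)
    assert chronic_ocs_flag(four_dates + [four_dates[0]], UK) is True
    assert chronic_ocs_flag(four_dates, UK) is False  # only 4 prescriptions
    assert chronic_ocs_flag(_dates(0, 0, 40, 40, 80), UK) is False  # 3 distinct dates


def test_chronic_ocs_prescription_threshold_configurable():
    four_dates = _dates(0, 40, 80, 120)
    assert chronic_ocs_flag(four_dates, UK, prescription_threshold=4) is True


def test_chronic_ocs_dispensation_needs_four_dates_in_two_quarters():
    assert chronic_ocs_flag(_dates(0, 30, 60, 100), FR) is True  # Q1 + Q2
    assert chronic_ocs_flag(_dates(0, 20, 40, 60), FR) is False  # all Q1
    assert chronic_ocs_flag(_dates(0, 100), FR) is False  # two dates only
    # five events but three distinct dates, two quarters: still below
    assert chronic_ocs_flag(_dates(0, 0, 40, 100, 100), FR) is False


# --- exclusion cascade via build_cohort -----------------------------------


def _qualifying_events(pid, saba_code, dates=None):
    dates = dates or [date(2013, 2, 1), date(2013, 3, 1), date(2013, 4, 1)]
    return [(pid, d, saba_code, 1) for d in dates]


def _one_patient_build(age, med_rows, dx_rows=None, dialect=FR, **cfg_kw):
    patients = make_patients(
        [{"patient_id": "P1", "birth_date": date(2013 - age, 1, 1), "dialect": dialect.value}]
    )
    cfg = fr_config(dialect=dialect, **cfg_kw)
    return build_cohort(
        patients, make_med_events(med_rows), make_dx_events(dx_rows), cfg
    )


@pytest.mark.parametrize("age,included", [(5, False), (6, True), (40, True), (41, False)])
def test_age_band_edges(code_of, age, included):
    res = _one_patient_build(age, _qualifying_events("P1", code_of(DrugClass.SABA)))
    assert (len(res.members) == 1) is included
    if not included:
        assert res.exclusions.outcome.tolist() == [Outcome.AGE_OUT_OF_RANGE.value]


def test_omalizumab_in_lookback_excludes(code_of):
    rows = _qualifying_events("P1", code_of(DrugClass.SABA))
    rows.append(("P1", date(2013, 1, 10), code_of(DrugClass.OMALIZUMAB), 1))
    res = _one_patient_build(20, rows)
    assert res.exclusions.outcome.tolist() == [Outcome.OMALIZUMAB.value]


def test_omalizumab_on_entry_date_is_followup_not_lookback(code_of):
    rows = _qualifying_events("P1", code_of(DrugClass.SABA))
    rows.append(("P1", date(2013, 4, 1), code_of(DrugClass.OMALIZUMAB), 1))
    res = _one_patient_build(20, rows)
    assert len(res.members) == 1


def test_insufficient_followup_excludes(code_of):
    res = _one_patient_build(
        20,
        _qualifying_events("P1", code_of(DrugClass.SABA)),
        data_end_date=date(2013, 12, 1),  # 8 months after entry
    )
    assert res.exclusions.outcome.tolist() == [Outcome.INSUFFICIENT_FOLLOWUP.value]


def test_followup_boundary_exactly_twelve_months(code_of):
    rows = _qualifying_events("P1", code_of(DrugClass.SABA))
    included = _one_patient_build(20, rows, data_end_date=date(2014, 4, 1))
    assert len(included.members) == 1
    short = _one_patient_build(20, rows, data_end_date=date(2014, 3, 31))
    assert short.exclusions.outcome.tolist() == [Outcome.INSUFFICIENT_FOLLOWUP.value]


def test_tiotropium_without_ics_excludes_but_with_ics_does_not(code_of):
    rows = _qualifying_events("P1", code_of(DrugClass.SABA))
    rows.append(("P1", date(2013, 1, 15), code_of(DrugClass.TIOTROPIUM), 1))
    res = _one_patient_build(20, rows)
    assert res.exclusions.outcome.tolist() == [Outcome.COPD_OR_COPD_DRUG.value]

    rows_with_ics = rows + [("P1", date(2013, 1, 20), code_of(DrugClass.ICS_MONO), 1)]
    res2 = _one_patient_build(20, rows_with_ics)
    assert len(res2.members) == 1


def test_copd_ltc_flag_excludes_dispensation_dialect(terminology, code_of):
    from asthmaclaims import ConditionLabel

    copd = terminology.condition_codes_for(FR, ConditionLabel.COPD)[0]
    res = _one_patient_build(
        20,
        _qualifying_events("P1", code_of(DrugClass.SABA)),
        dx_rows=[("P1", date(2013, 1, 15), copd, "LTC_FLAG")],
    )
    assert res.exclusions.outcome.tolist() == [Outcome.COPD_OR_COPD_DRUG.value]


def test_prescription_dialect_requires_asthma_diagnosis(terminology):
    from asthmaclaims import ConditionLabel

    saba = terminology.drug_codes_for(UK, DrugClass.SABA)[0]
    res = _one_patient_build(20, _qualifying_events("P1", saba), dialect=UK)
    assert res.exclusions.outcome.tolist() == [Outcome.NO_ASTHMA_DIAGNOSIS.value]

    asthma = terminology.condition_codes_for(UK, ConditionLabel.ASTHMA)[0]
    res2 = _one_patient_build(
        20,
        _qualifying_events("P1", saba),
        dx_rows=[("P1", date(2013, 2, 1), asthma, "DIAGNOSIS")],
        dialect=UK,
    )
    assert len(res2.members) == 1


def test_first_triggering_rule_wins(code_of, terminology):
    # omalizumab precedes chronic OCS in the cascade
    from asthmaclaims import ConditionLabel

    rows = _qualifying_events("P1", code_of(DrugClass.SABA))
    rows.append(("P1", date(2013, 1, 10), code_of(DrugClass.OMALIZUMAB), 1))
    ocs = code_of(DrugClass.OCS)
    rows += [("P1", date(2012, 5, 1) + timedelta(days=40 * i), ocs, 1) for i in range(4)]
    res = _one_patient_build(20, rows)
    assert res.exclusions.outcome.tolist() == [Outcome.OMALIZUMAB.value]


def test_every_patient_gets_exactly_one_outcome(code_of):
    patients = make_patients(
        [
            {"patient_id": "P1", "birth_date": date(1993, 1, 1)},
            {"patient_id": "P2", "birth_date": date(1993, 1, 1)},
        ]
    )
    med = make_med_events(_qualifying_events("P1", code_of(DrugClass.SABA)))
    res = build_cohort(patients, med, make_dx_events(), fr_config())
    assert sorted(res.members.patient_id.tolist() + res.exclusions.patient_id.tolist()) == [
        "P1",
        "P2",
    ]


def test_row_order_invariance(code_of):
    rows = _qualifying_events("P1", code_of(DrugClass.SABA)) + _qualifying_events(
        "P2", code_of(DrugClass.SABA), [date(2013, 5, 1), date(2013, 6, 1), date(2013, 7, 1)]
    )
    rows.append(("P2", date(2013, 2, 10), code_of(DrugClass.OMALIZUMAB), 1))
    patients = make_patients(
        [
            {"patient_id": "P1", "birth_date": date(1993, 1, 1)},
            {"patient_id": "P2", "birth_date": date(1993, 1, 1)},
        ]
    )
    base = build_cohort(patients, make_med_events(rows), make_dx_events(), fr_config())
    shuffled = make_med_events(rows).sample(frac=1.0, random_state=3)
    alt = build_cohort(
        patients.sample(frac=1.0, random_state=4), shuffled, make_dx_events(), fr_config()
    )
    pd.testing.assert_frame_equal(base.members, alt.members)
    pd.testing.assert_frame_equal(
        base.exclusions.sort_values("patient_id").reset_index(drop=True),
        alt.exclusions.sort_values("patient_id").reset_index(drop=True),
    )


# --- baseline table -------------------------------------------------------


def _baseline_value(table, statistic):
    return table.set_index("statistic").loc[statistic, "value"]


def test_baseline_percentages_round_half_up():
    members = pd.DataFrame(
        {
            "patient_id": [f"P{i}" for i in range(8)],
            "age_at_entry": [8, 9, 10, 20, 21, 22, 23, 24],
            "age_group": ["CHILD_6_13"] * 3 + ["ADULT_14_40"] * 5,
            "sex": ["M", "F", "M", "F", "M", "F", "M", "F"],
        }
    )
    table = baseline_table(members)
    assert _baseline_value(table, "n") == 8
    assert _baseline_value(table, "children_pct") == 37.5
    assert _baseline_value(table, "males_pct") == 50.0
    assert _baseline_value(table, "mean_age") == pytest.approx(17.125)


def test_baseline_empty_cohort_has_no_division_by_zero():
    table = baseline_table(pd.DataFrame(columns=["patient_id", "age_at_entry", "age_group", "sex"]))
    assert _baseline_value(table, "n") == 0
    assert pd.isna(_baseline_value(table, "children_pct"))


def test_baseline_all_male_cohort_is_100_percent():
    members = pd.DataFrame(
        {
            "patient_id": ["P1", "P2"],
            "age_at_entry": [20, 30],
            "age_group": ["ADULT_14_40", "ADULT_14_40"],
            "sex": ["M", "M"],
        }
    )
    assert _baseline_value(baseline_table(members), "males_pct") == 100.0


# --- small-instance oracle ------------------------------------------------


def _random_microdb(rng, terminology, dialect, year=2013):
    """A random <=20-patient database stressing windows and edge dates."""
    n = int(rng.integers(1, 21))
    drug_codes = sorted(terminology.drug_map) + ["UNKNOWN1"]
    cond_codes = sorted(terminology.condition_map) + ["UNKNOWNC"]
    sources = ["DIAGNOSIS", "LTC_FLAG", "HOSPITAL_DISCHARGE"]
    start = date(year - 1, 1, 1)
    span = (date(year + 1, 12, 31) - start).days
    patients, med, dx = [], [], []
    for i in range(n):
        pid = f"M{i:03d}"
        birth = date(
            int(year - rng.integers(3, 46)), int(rng.integers(1, 13)), int(rng.integers(1, 29))
        )
        patients.append(
            {"patient_id": pid, "birth_date": birth, "sex": "M", "dialect": dialect.value}
        )
        for _ in range(int(rng.integers(0, 10))):
            med.append(
                (
                    pid,
                    start + timedelta(days=int(rng.integers(span))),
                    drug_codes[int(rng.integers(len(drug_codes)))],
                    int(rng.integers(1, 4)),
                )
            )
        for _ in range(int(rng.integers(0, 3))):
            dx.append(
                (
                    pid,
                    start + timedelta(days=int(rng.integers(span))),
                    cond_codes[int(rng.integers(len(cond_codes)))],
                    sources[int(rng.integers(3))],
                )
            )
    data_end = date(year + 1, int(rng.integers(1, 13)), int(rng.integers(1, 29)))
    return make_patients(patients), make_med_events(med), make_dx_events(dx), data_end


@pytest.mark.parametrize("dialect", [FR, UK])
def test_microdatabases_match_naive_enumerator(terminology, dialect):
    rng = np.random.default_rng(20130 + (dialect is UK))
    for _ in range(100):
        patients, med, dx, data_end = _random_microdb(rng, terminology, dialect)
        cfg = CohortConfig(dialect=dialect, cohort_year=2013, data_end_date=data_end)
        res = build_cohort(patients, med, dx, cfg, terminology)
        got = {
            **dict(zip(res.exclusions.patient_id, res.exclusions.outcome)),
            **{pid: "INCLUDED" for pid in res.members.patient_id},
        }
        entries = dict(zip(res.members.patient_id, res.members.entry_date))
        for p in patients.itertuples(index=False):
            p_med = [
                (r.date, terminology.classify_drug(r.drug_code).value)
                for r in med.itertuples(index=False)
                if r.patient_id == p.patient_id
            ]
            p_dx = [
                (r.date, terminology.classify_condition(r.condition_code).value)
                for r in dx.itertuples(index=False)
                if r.patient_id == p.patient_id
            ]
            expected, entry = naive_outcome(
                p.birth_date, p_med, p_dx, dialect.value, 2013, data_end
            )
            assert got[p.patient_id] == expected, p.patient_id
            if expected == "INCLUDED":
                assert entries[p.patient_id] == entry
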