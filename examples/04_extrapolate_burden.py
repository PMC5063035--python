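"""Scale cohort prevalences to a national burden estimate.

Takes pattern prevalences measured in a simulated cohort and extrapolates
them to a national population by direct standardisation: national count =
cohort prevalence x national asthma prevalence (ages 6-40) x national
population (ages 6-40).  The national figures are external inputs, here
chosen as round illustrative values.
"""

from asthmaclaims import (
    CohortConfig,
    Dialect,
    NationalInputs,
    SimulationConfig,
    build_cohort,
    classify_cohort,
    extrapolate_all,
    generate,
)

sim = SimulationConfig(
    seed=42, n_patients=2000, dialect=Dialect.DISPENSATION_FR_LIKE, cohort_year=2013
)
tables = generate(sim)
cohort = build_cohort(
    tables.patients,
    tables.med_events,
    tables.dx_events,
    CohortConfig(dialect=sim.dialect, cohort_year=2013, data_end_date=sim.data_end_date),
)
_, prevalence = classify_cohort(cohort.members, tables.med_events)

overall = prevalence[prevalence.stratum == "ALL"].set_index("pattern")
proportions = {
    p: float(overall.loc[p, "n_flagged"]) / float(overall.loc[p, "n"])
    for p in overall.index
}

national = NationalInputs(
    country="Illustria",
    year=2013,
    population_6_40=28_000_000,
    asthma_prevalence_6_40=0.077,
    rounding_granularity=10,
)
result = extrapolate_all(proportions, national)

print(f"cohort prevalences: { {k: round(v, 4) for k, v in proportions.items()} }")
print(f"national asthma population 6-40: "
      f"{national.population_6_40 * national.asthma_prevalence_6_40:,.0f}")
print()
print(f"extrapolated patients with SABA overuse:      {result.saba_overuse:>9,}")
print(f"extrapolated patients with LABA without ICS:  {result.laba_no_ics:>9,}")
print(f"extrapolated patients with unbalanced LABA:   {result.laba_unbalanced:>9,}")
print(f"total inappropriately treated (6-40 years):   {result.total:>9,}")
# The total is the exact sum of the three per-pattern counts; each count is
# rounded to the configured granularity (here the nearest 10) beforehand.
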