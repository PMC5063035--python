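"""Generate a synthetic dispensation-style claims database.

Builds a 500-patient French-claims-style extract for a 2013 cohort with the
default planted prevalences (10% SABA overuse, 2% LABA without ICS, 2%
unbalanced LABA/ICS among eligible patients) and prints the table shapes and
the planted truth composition.
"""

from asthmaclaims import Dialect, SimulationConfig, generate

config = SimulationConfig(
    seed=42, n_patients=500, dialect=Dialect.DISPENSATION_FR_LIKE, cohort_year=2013
)
tables = generate(config)

print(f"patients:   {len(tables.patients)} rows")
print(f"med_events: {len(tables.med_events)} pack-events")
print(f"dx_events:  {len(tables.dx_events)} condition records")
print()
print("planted selection outcomes (ground truth):")
print(tables.truth.reason.value_counts().to_string())
# Each patient is planted constructively: the events written to the tables
# realise exactly the outcome and patterns recorded in the truth table, so a
# correct cohort builder must recover this composition patient for patient.
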