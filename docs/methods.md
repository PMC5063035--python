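# Methods

This note documents the models and procedures implemented in
`asthmaclaims`, the conventions chosen where a claims-analysis design is
genuinely open, and what the synthetic-data validation does and does not
demonstrate.

## Data model

The pipeline operates on pack-level medication events: one row per
prescribed (prescription dialect) or dispensed (dispensation dialect) pack
of a coded drug, with a date and a pack count.  Treatment units are packs
throughout; no dose, strength or days-supply information is used.  Drug and
condition codes are opaque strings resolved through a terminology table
(CSV: `code, dialect, class_label, human_name`); the shipped default is a
deliberately miniature registry — at least two codes per therapeutic class
and dialect, ATC-like codes for the dispensation dialect and Read-like
codes for the prescription dialect — sufficient to exercise many-to-one
code→class mapping, not a reproduction of any real dictionary.  Unmapped
codes classify as OTHER (logged once per code) and can never qualify,
exclude or flag a patient.

## Cohort selection

- **Entry.** The entry date is the third distinct calendar date in the
  cohort year bearing at least one respiratory-drug event (SABA, single
  LABA, single ICS, fixed-dose ICS/LABA, LTRA, xanthine).  Multiple
  events on one date count once.
- **Windows.** Lookback is `[entry − 12 months, entry)` and follow-up
  `[entry, entry + 12 months)`: both half-open, with the entry date itself
  in follow-up (the third qualifying event is exposure).  "12 months"
  means the same day-of-month one year away, clamped to month end
  (Feb 29 + 12 m → Feb 28).  Calendar quarters are civil quarters.
- **Age.** Completed years at entry; the eligible band is 6–40 inclusive,
  stratified as children 6–13 and adults 14–40.
- **Chronic OCS.** Prescription dialect: ≥ 5 OCS prescription events on
  ≥ 4 distinct lookback dates.  The threshold of 5 is the strict reading
  of "more than 4"; it is configurable
  (`CohortConfig.ocs_prescription_threshold=4` gives the inclusive
  reading).  Dispensation dialect: OCS dispensations on ≥ 4 distinct dates
  spanning ≥ 2 civil quarters.
- **COPD by drug proxy.** "Tiotropium or indacaterol alone" is evaluated
  at patient-window granularity: excluded iff the lookback window holds at
  least one tiotropium/indacaterol event and no ICS-containing event.
- **Asthma diagnosis (prescription dialect only).** At least one coded
  asthma diagnosis on or before the entry date.  The requirement is
  checked right after entry-date determination — it is an inclusion
  criterion, so it precedes the exclusion cascade — and failing it is
  reported as its own outcome (`NO_ASTHMA_DIAGNOSIS`).
- **Ordering.** Exclusions are evaluated in a fixed order (age band,
  omalizumab, chronic OCS, COPD/COPD-drug, cystic fibrosis, lung cancer,
  bronchiectasis, tuberculosis, sarcoidosis, follow-up coverage) and only
  the first triggered reason is reported, giving reproducible reason
  attribution.  Exclusion conditions are scanned in the lookback window
  only; events after entry never retro-exclude a patient.
- **Follow-up coverage.** A patient needs `data_end_date ≥ entry + 12
  months`, where `data_end_date` is the configured end of data collection
  for the extract.

## Pattern definitions

Over each member's follow-up window, packs are summed by class
(`U_SABA, U_LABA, U_ICS, U_FDC`, plus LTRA and xanthine for description):

| pattern | rule |
|---|---|
| SABA overuse | `U_SABA ≥ 12` |
| LABA without ICS | `U_LABA ≥ 1` and `U_ICS + U_FDC = 0` |
| Unbalanced LABA/ICS | `U_ICS ≥ 1` and `U_LABA ≥ 2·U_ICS` |

`U_LABA` counts single-agent LABA only; fixed-dose combination packs count
as ICS co-therapy and never as LABA exposure, because the combination
device guarantees the ICS the two LABA patterns screen for.  The ratio
pattern requires `U_ICS ≥ 1`: a patient with LABA, no single ICS and no
FDC belongs to "LABA without ICS"; with LABA, no single ICS but some FDC,
the ratio is undefined and ICS co-therapy is present, so neither LABA
pattern fires.  This keeps the two flags mutually exclusive, matching
their separate reporting.  ICS *underuse* is deliberately out of scope: it
cannot be assessed without clinical context separating persistent from
intermittent asthma.

Prevalences are reported per stratum as percentages rounded half-up to one
decimal (`round` alone would round half-even).  The baseline table reports
N, mean age with the n−1 standard deviation, and counts/percentages for
age groups and sex; the s.d. of a single value is reported missing, not
zero.

## Statistical comparisons

Percentages are compared with Pearson's χ² on the 2×2 table (df = 1).
Continuity correction is off by default — the intended cohorts have
thousands of members — but switchable per call and on the CLI.  A zero
table margin makes the test undefined and raises a dedicated error rather
than returning NaN.  Continuous variables use the two-sided Mann–Whitney U
test: exact enumeration of the U distribution for small untied samples
(`n₁·n₂ ≤ 64`), otherwise a normal approximation with tie-corrected
variance and a continuity correction truncated at the distribution's
center, `z = max(0, |U − μ| − ½)/σ`.  The truncation makes identical
samples give p = 1 exactly while keeping the approximation within about
0.01 of exact enumeration at n = 8/8 (plain no-continuity normal p-values
deviate from exact by up to ~0.05 there).  Significance is read at
p < 0.05, two-sided; no multiple-testing adjustment is applied, and none
is claimed.

## Extrapolation

National burden is a direct standardisation:
`count = cohort prevalence × national asthma prevalence (6–40) × national
population (6–40)`.  Both national figures are configuration inputs —
they come from national statistics and disease registers, and hard-coding
them would fabricate data the package cannot verify.  Per-pattern counts
may be rounded to a configurable granularity (e.g. nearest 10) but
granularity 1 (no rounding) is the default, and the total is always the
exact sum of its three components.  When strata must be pooled before
extrapolation, `weighted_cohort_prevalence` forms the convex combination
of stratum prevalences weighted by cohort shares; a single pooled asthma
prevalence is used by default, stratum-specific inputs being a
caller-side choice.

## Synthetic claims generator

The generator plants outcomes constructively.  Per patient, in one
documented pseudo-random stream (numpy `default_rng(seed)`): sex, then an
integer age at cohort-year start (birth date back-computed to 1 January,
avoiding leap-day ambiguity), then a selection channel — ineligible by
age if the drawn age falls outside 6–40, otherwise one of the exclusion
channels with the configured rates, otherwise eligible — then, for
eligible patients, independent Bernoulli draws for SABA overuse and a
three-way categorical draw for the LABA patterns (none / without-ICS /
unbalanced, making the two mutually exclusive by design).  Events are then
written to realise exactly that assignment: three distinct qualifying
dates with the third (the entry date) no later than `data_end − 12
months` for patients meant to have full follow-up; pattern-consistent
follow-up pack budgets (≥ 12 + Poisson(3) SABA packs for overuse, 1–8
otherwise; LABA/ICS/FDC budgets satisfying or avoiding each LABA rule);
and exclusion triggers placed inside the lookback window (e.g. OCS events
at entry − 10, − 7, − 4, − 1 months, which spans ≥ 2 quarters by
construction).  Only the two planned pre-entry dates carry respiratory
events before entry, so the realised entry date always equals the planted
one.

Defaults describe one fixed study condition: 10% SABA overuse, 2% LABA
without ICS and 2% unbalanced use among eligible patients (pattern
prevalences of the magnitude seen in drug-utilization studies of asthma,
with SABA overuse dominating); ~5% of patients with too few respiratory
dates, ~6% with out-of-band ages, and 0.5–2% per exclusion channel; a
52% male ratio; pack sizes 1/2/3 with weights 0.7/0.2/0.1; and data
coverage through 31 October of the following year so that late-year
entries can be planted as insufficient follow-up.

What this emulates is the *structure* of claims data — two dialects'
event channels, windowing, rule edge cases.  What it does not emulate:
seasonality, adherence dynamics, prescriber clustering, unfilled
prescriptions, coding noise, or marginals calibrated to any real
database.  Passing the plant-recovery and prevalence tests therefore
demonstrates that the rules are implemented correctly, not that any
particular real-world prevalence is expected.

## Validation strategy

- **Exact plant recovery.** On 2,000-patient runs in each dialect, the
  cohort builder's inclusion decision, exclusion reason and entry date
  must match the planted truth for every patient, and each measured
  pattern prevalence must lie in the exact binomial 99% CI around its
  planted value.
- **Independent oracles.** The selection algorithm is checked against a
  naive enumerator written on a different calendar implementation
  (`dateutil.relativedelta`) over hundreds of randomly generated ≤ 20-
  patient micro-databases; pattern flags are checked against a brute-force
  reading of the printed definitions over a full count grid; the exact
  Mann–Whitney p-value is checked against complete enumeration of
  labelings; χ² against the closed-form Σ(O−E)²/E.
- **Published arithmetic.** Burden totals and baseline percentages are
  recomputed from published per-pattern counts and stratum counts.
- **Calibration.** Simulated-null type-I error of the χ² comparison at
  α = 0.05 must lie in [0.035, 0.065] over 5,000 replicates.

Problem sizes (2,000 patients per dialect, 200 micro-databases, 5,000 null
replicates) keep the whole suite under a minute while leaving the binomial
and calibration checks well-powered.

## Known limitations

- The terminology is miniature; real studies need full ATC/Read code
  lists, and edge classes (e.g. LABA+LAMA combinations) are deliberately
  absent pending a defensible class assignment.
- Only one entry per patient per cohort year is considered; re-entry and
  censoring dynamics are out of scope.
- Hospital-discharge condition records are a simple code channel, not a
  linked episode model.
- Extrapolation carries no uncertainty interval; it propagates the point
  prevalence only.
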