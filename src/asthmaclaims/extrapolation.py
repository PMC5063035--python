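"""National burden extrapolation by direct standardisation.

A cohort-level pattern prevalence is scaled to a national count of affected
patients:

    count = pattern_prevalence x asthma_prevalence_6_40 x population_6_40

National population and asthma prevalence are configuration inputs (they
come from national statistics offices and disease registers, not from the
claims extract) and are never fetched by the package.  Per-pattern counts
can optionally be rounded to a granularity (e.g. the nearest 10); by
default no rounding is applied and totals are exact sums of their three
components.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from pydantic import BaseModel, Field

from ._rounding import round_to_multiple

PATTERN_KEYS = ("saba_overuse", "laba_no_ics", "laba_unbalanced")


class NationalInputs(BaseModel):
    """External figures for one country-year extrapolation."""

    country: str
    year: int = Field(ge=1900, le=2100)
    population_6_40: int = Field(gt=0, description="national residents aged 6-40")
    asthma_prevalence_6_40: float = Field(
        ge=0.0, le=1.0, description="asthma prevalence in the 6-40 age band"
    )
    rounding_granularity: int = Field(
        default=1, ge=1, description="per-pattern counts round to this multiple"
    )


@dataclass(frozen=True)
class ExtrapolationResult:
    country: str
    year: int
    saba_overuse: int
    laba_no_ics: int
    laba_unbalanced: int
    total: int


def extrapolate_pattern(pattern_prevalence: float, inputs: NationalInputs) -> int:
    """National count of patients exposed to one inappropriate pattern."""
    if not 0.0 <= pattern_prevalence <= 1.0:
        raise ValueError("pattern prevalence must lie in [0, 1]")
    raw = (
        pattern_prevalence
        * inputs.asthma_prevalence_6_40
        * inputs.population_6_40
    )
    return round_to_multiple(raw, inputs.rounding_granularity)


def total_burden(saba_overuse: int, laba_no_ics: int, laba_unbalanced: int) -> int:
    """Total inappropriately treated patients: exact sum of the components."""
    return int(saba_overuse) + int(laba_no_ics) + int(laba_unbalanced)


def extrapolate_all(
    prevalences: Mapping[str, float], inputs: NationalInputs
) -> ExtrapolationResult:
    """Extrapolate all three patterns and their total for one country-year.

    ``prevalences`` maps each pattern key (saba_overuse, laba_no_ics,
    laba_unbalanced) to its cohort proportion in [0, 1].
    """
    missing = [k for k in PATTERN_KEYS if k not in prevalences]
    if missing:
        raise KeyError(f"missing pattern prevalences: {missing}")
    counts = {k: extrapolate_pattern(prevalences[k], inputs) for k in PATTERN_KEYS}
    return ExtrapolationResult(
        country=inputs.country,
        year=inputs.year,
        total=total_burden(*counts.values()),
        **counts,
    )


def weighted_cohort_prevalence(
    child_prevalence: float,
    adult_prevalence: float,
    child_share: float,
    adult_share: float,
) -> float:
    """Combine stratum prevalences into one cohort proportion.

    Convex combination weighted by the strata's shares of the cohort; the
    shares must sum to 1 within 1e-9.
    """
    if abs(child_share + adult_share - 1.0) > 1e-9:
        raise ValueError("stratum shares must sum to 1")
    if min(child_share, adult_share) < 0:
        raise ValueError("stratum shares must be non-negative")
    return child_share * child_prevalence + adult_share * adult_prevalence
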