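"""Descriptive and comparative statistics for cohort comparisons.

Percentages are compared with Pearson's chi-squared test on the 2x2 table
(continuity correction off by default, switchable), continuous variables
with the Mann-Whitney U test; two-sided throughout, significance read at
p < 0.05, no multiple-testing adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._rounding import round_half_up

#: Significance threshold used when annotating comparison tables.
ALPHA = 0.05

#: Largest n1*n2 for which the Mann-Whitney p-value is computed by exact
#: enumeration of the U distribution (ties always fall back to the normal
#: approximation with tie-corrected variance).
EXACT_MW_LIMIT = 64


class UndefinedTestError(ValueError):
    """The requested test is undefined for the given table (zero margin)."""


@dataclass(frozen=True)
class ProportionComparison:
    group_a: str
    group_b: str
    flagged_a: int
    n_a: int
    flagged_b: int
    n_b: int
    statistic: float
    df: int
    p_value: float
    continuity_correction: bool

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


@dataclass(frozen=True)
class RankComparison:
    group_a: str
    group_b: str
    u_statistic: float
    p_value: float
    method: str  # "exact" or "normal"
    tie_correction_applied: bool


@dataclass(frozen=True)
class Summary:
    mean: float
    sd: float | None  # None for a single observation (undefined, not zero)
    n: int


def compare_proportions(
    flagged_a: int,
    n_a: int,
    flagged_b: int,
    n_b: int,
    labels: tuple[str, str] = ("A", "B"),
    continuity: bool = False,
) -> ProportionComparison:
    """Pearson chi-squared test of two proportions on the 2x2 table, df=1.

    Raises :class:`UndefinedTestError` when a table margin is zero (an
    expected cell count of zero), e.g. nobody flagged in either group.
    """
    if n_a < 1 or n_b < 1:
        raise UndefinedTestError("both groups must be non-empty")
    if not (0 <= flagged_a <= n_a and 0 <= flagged_b <= n_b):
        raise ValueError("flagged counts must lie in [0, n]")
    table = np.array(
        [[flagged_a, n_a - flagged_a], [flagged_b, n_b - flagged_b]], dtype=float
    )
    if (table.sum(axis=0) == 0).any():
        raise UndefinedTestError(
            "chi-squared test undefined: a table margin is zero "
            f"(column sums {table.sum(axis=0).astype(int).tolist()})"
        )
    res = sps.chi2_contingency(table, correction=continuity)
    return ProportionComparison(
        group_a=labels[0],
        group_b=labels[1],
        flagged_a=flagged_a,
        n_a=n_a,
        flagged_b=flagged_b,
        n_b=n_b,
        statistic=float(res.statistic),
        df=int(res.dof),
        p_value=float(res.pvalue),
        continuity_correction=continuity,
    )


def compare_ranks(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    labels: tuple[str, str] = ("A", "B"),
    method: str = "auto",
) -> RankComparison:
    """Two-sided Mann-Whitney U test; U is reported for ``sample_a``.

    With ``method="auto"``, small untied samples (n1*n2 <= 64) get an exact
    p-value by enumeration of the U distribution; everything else uses the
    normal approximation with tie-corrected variance and a continuity
    correction truncated at the center of the distribution
    (z = max(0, |U - mu| - 1/2) / sigma), so that identical samples give
    p = 1 exactly while the approximation still tracks the discrete exact
    distribution closely.  ``method`` may force ``"exact"`` (untied data
    only) or ``"normal"``.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if method == "auto":
        method = "exact" if (n1 * n2 <= EXACT_MW_LIMIT and not has_ties) else "normal"
    elif method == "exact" and has_ties:
        raise ValueError("exact enumeration requires untied data")
    elif method not in ("exact", "normal"):
        raise ValueError(f"unknown method {method!r}")

    ranks = sps.rankdata(pooled)  # midranks under ties
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)

    if method == "exact":
        p = float(
            sps.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
        )
    else:
        n = n1 + n2
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = float((tie_counts**3 - tie_counts).sum())
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        if var <= 0:  # every pooled value identical
            p = 1.0
        else:
            z = max(0.0, abs(u1 - n1 * n2 / 2.0) - 0.5) / np.sqrt(var)
            p = float(min(1.0, 2.0 * sps.norm.sf(z)))
    return RankComparison(
        group_a=labels[0],
        group_b=labels[1],
        u_statistic=u1,
        p_value=p,
        method=method,
        tie_correction_applied=(method == "normal") and has_ties,
    )


def summarize(values: Sequence[float]) -> Summary:
    """Mean, sample (n-1) standard deviation and count of a numeric vector."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty vector")
    sd = float(arr.std(ddof=1)) if arr.size > 1 else None
    return Summary(mean=float(arr.mean()), sd=sd, n=int(arr.size))


def tabulate(labels: Sequence) -> pd.DataFrame:
    """Counts and half-up 1-decimal percentages of a categorical vector."""
    series = pd.Series(list(labels))
    counts = series.value_counts().sort_index()
    total = int(counts.sum())
    return pd.DataFrame(
        {
            "level": counts.index,
            "count": counts.to_numpy(),
            "percent": [round_half_up(100.0 * c / total, 1) for c in counts],
        }
    ).reset_index(drop=True)


def percent(count: int, total: int) -> float:
    """Report-table percentage: half-up rounded to one decimal place."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round_half_up(100.0 * count / total, 1)


def compare_prevalence_tables(
    prevalence_a: pd.DataFrame,
    prevalence_b: pd.DataFrame,
    labels: tuple[str, str] = ("A", "B"),
    continuity: bool = False,
) -> pd.DataFrame:
    """Chi-squared comparison of two stratified prevalence tables.

    Both inputs follow the ``classify_cohort`` prevalence schema (stratum,
    pattern, n, n_flagged, percent).  Rows whose test is undefined (zero
    margin) carry missing statistic and p-value.
    """
    merged = prevalence_a.merge(
        prevalence_b, on=["stratum", "pattern"], suffixes=("_a", "_b")
    )
    rows = []
    for r in merged.itertuples(index=False):
        chi2 = dof = p = None
        if r.n_a > 0 and r.n_b > 0:
            try:
                cmp_res = compare_proportions(
                    r.n_flagged_a, r.n_a, r.n_flagged_b, r.n_b,
                    labels=labels, continuity=continuity,
                )
                chi2, dof, p = cmp_res.statistic, cmp_res.df, cmp_res.p_value
            except UndefinedTestError:
                pass
        rows.append(
            {
                "stratum": r.stratum,
                "pattern": r.pattern,
                "pct_a": r.percent_a,
                "pct_b": r.percent_b,
                "chi2": chi2,
                "df": dof,
                "p": p,
            }
        )
    return pd.DataFrame(rows, columns=["stratum", "pattern", "pct_a", "pct_b", "chi2", "df", "p"])
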