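"""Independent brute-force oracles used by the test suite.

Deliberately naive re-implementations of the selection and pattern rules,
kept free of any package internals: calendar arithmetic goes through
``dateutil.relativedelta`` instead of the package's month arithmetic, rules
are evaluated by direct enumeration, and the Mann-Whitney p-value is
computed by exhaustive enumeration of labelings.
"""

from __future__ import annotations

from datetime import date
from itertools import combinations

from dateutil.relativedelta import relativedelta

RESPIRATORY = {"SABA", "LABA_MONO", "ICS_MONO", "FDC_ICS_LABA", "LTRA", "XANTHINE"}
ICS_CONTAINING = {"ICS_MONO", "FDC_ICS_LABA"}


def naive_outcome(
    birth_date: date,
    med: list[tuple[date, str]],
    dx: list[tuple[date, str]],
    dialect: str,
    year: int,
    data_end: date,
    ocs_threshold: int = 5,
) -> tuple[str, date | None]:
    """Selection outcome and entry date for one patient, evaluated naively.

    ``med`` holds (date, drug-class-name) pairs, ``dx`` (date,
    condition-label) pairs.
    """
    resp_dates = sorted({d for d, c in med if d.year == year and c in RESPIRATORY})
    if len(resp_dates) < 3:
        return "NOT_ENOUGH_EVENTS", None
    entry = resp_dates[2]

    if dialect == "PRESCRIPTION_UK_LIKE" and not any(
        lbl == "ASTHMA" and d <= entry for d, lbl in dx
    ):
        return "NO_ASTHMA_DIAGNOSIS", entry

    lb_start = entry - relativedelta(months=12)

    def in_lookback(d: date) -> bool:
        return lb_start <= d < entry

    age = relativedelta(entry, birth_date).years
    if age < 6 or age > 40:
        return "AGE_OUT_OF_RANGE", entry

    if any(c == "OMALIZUMAB" and in_lookback(d) for d, c in med):
        return "OMALIZUMAB", entry

    ocs = [d for d, c in med if c == "OCS" and in_lookback(d)]
    if dialect == "PRESCRIPTION_UK_LIKE":
        chronic = len(ocs) >= ocs_threshold and len(set(ocs)) >= 4
    else:
        quarters = {(d.year, (d.month - 1) // 3) for d in set(ocs)}
        chronic = len(set(ocs)) >= 4 and len(quarters) >= 2
    if chronic:
        return "CHRONIC_OCS", entry

    copd_coded = any(lbl == "COPD" and in_lookback(d) for d, lbl in dx)
    copd_drug = any(
        c in ("TIOTROPIUM", "INDACATEROL") and in_lookback(d) for d, c in med
    ) and not any(c in ICS_CONTAINING and in_lookback(d) for d, c in med)
    if copd_coded or copd_drug:
        return "COPD_OR_COPD_DRUG", entry

    for label, outcome in (
        ("CYSTIC_FIBROSIS", "CF"),
        ("LUNG_CANCER", "LUNG_CANCER"),
        ("BRONCHIECTASIS", "BRONCHIECTASIS"),
        ("TUBERCULOSIS", "TB"),
        ("SARCOIDOSIS", "SARCOIDOSIS"),
    ):
        if any(lbl == label and in_lookback(d) for d, lbl in dx):
            return outcome, entry

    if data_end < entry + relativedelta(months=12):
        return "INSUFFICIENT_FOLLOWUP", entry

    return "INCLUDED", entry


def brute_flags(saba: int, laba: int, ics: int, fdc: int) -> tuple[bool, bool, bool]:
    """Pattern flags straight from the printed definitions.

    Overuse: 12 or more reliever packs.  LABA without ICS: any single LABA
    with no ICS in any form.  Unbalanced: the LABA/single-ICS pack ratio is
    at least 2, evaluated as an actual division (only defined for ics > 0).
    """
    overuse = saba >= 12
    no_ics = laba >= 1 and ics == 0 and fdc == 0
    unbalanced = ics > 0 and (laba / ics) >= 2.0
    return overuse, no_ics, unbalanced


def pearson_chi2(a: int, b: int, c: int, d: int) -> float:
    """Chi-squared statistic of the 2x2 table [[a, b], [c, d]] by Sum(O-E)^2/E."""
    n = a + b + c + d
    stat = 0.0
    rows = (a + b, c + d)
    cols = (a + c, b + d)
    for i, obs_row in enumerate(((a, b), (c, d))):
        for j, obs in enumerate(obs_row):
            expected = rows[i] * cols[j] / n
            stat += (obs - expected) ** 2 / expected
    return stat


def brute_mw(a: list[float], b: list[float]) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney (U for ``a``, p) by full enumeration.

    Enumerates all C(n1+n2, n1) assignments of the pooled values to group a
    and counts assignments at least as extreme (in |U - n1*n2/2|) as the
    observed one.  Untied data only.
    """
    pooled = sorted(a + b)
    n1, n2 = len(a), len(b)

    def u_pairs(xs: list[float], ys: list[float]) -> float:
        return float(sum(1 for x in xs for y in ys if x > y))

    u_obs = u_pairs(list(a), list(b))
    center = n1 * n2 / 2.0
    extreme = 0
    total = 0
    for combo in combinations(range(n1 + n2), n1):
        sel = set(combo)
        xs = [pooled[i] for i in combo]
        ys = [pooled[i] for i in range(n1 + n2) if i not in sel]
        u = u_pairs(xs, ys)
        total += 1
        if abs(u - center) >= abs(u_obs - center):
            extreme += 1
    return u_obs, min(1.0, extreme / total)
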