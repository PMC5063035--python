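"""Calendar arithmetic used throughout the pipeline.

All windowing in the package is expressed in calendar months with one
deterministic rule: adding N months keeps the day-of-month, clamped to the
last day of the target month (Jan 31 + 1 month = Feb 28/29).  Age is counted
in completed years at a reference date.  Quarters are civil-calendar quarters
(Jan-Mar, Apr-Jun, Jul-Sep, Oct-Dec).
"""

from __future__ import annotations

import calendar
from datetime import date


def add_months(d: date, n: int) -> date:
    """Shift a date by ``n`` calendar months, clamping to month end."""
    months = d.month - 1 + n
    year = d.year + months // 12
    month = months % 12 + 1
    day = min(d.day, calendar.monthrange(year, month)[1])
    return date(year, month, day)


def quarter_of(d: date) -> tuple[int, int]:
    """Civil calendar quarter as (year, quarter 1-4)."""
    return d.year, (d.month - 1) // 3 + 1


def completed_years(birth_date: date, on: date) -> int:
    """Age in completed years on a given date (standard epidemiological age)."""
    years = on.year - birth_date.year
    if (on.month, on.day) < (birth_date.month, birth_date.day):
        years -= 1
    return years
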