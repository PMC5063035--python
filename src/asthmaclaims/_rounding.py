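"""Half-up decimal rounding for report tables.

Python's built-in ``round`` uses banker's rounding; published claims-study
tables round half away from zero, so percentages and extrapolated counts go
through these helpers instead.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 0) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def round_to_multiple(x: float, granularity: int) -> int:
    """Round half-up to the nearest multiple of ``granularity`` (>= 1)."""
    if granularity < 1:
        raise ValueError("granularity must be a positive integer")
    return int(round_half_up(x / granularity, 0)) * granularity
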