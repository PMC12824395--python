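"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero at ``ndigits`` decimals (printed-table
    convention, unlike banker's rounding)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percent(count: float, denom: float, ndigits: int = 1) -> float:
    """count / denom as a percentage rounded half-up."""
    if denom == 0:
        return float("nan")
    return round_half_up(100.0 * count / denom, ndigits)
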