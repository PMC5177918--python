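"""Small shared numeric helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_away(value: float, decimals: int = 0) -> float:
    """Round half away from zero (the convention of printed percentages).

    Python's builtin ``round`` is banker's rounding; report-facing numbers
    like 95.45 -> 95.5 need the away-from-zero rule instead.
    """
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def percent(count: int, universe: int, decimals: int = 1) -> float:
    """100*count/universe rounded half away from zero to ``decimals`` places."""
    if universe <= 0:
        raise ValueError("universe must be positive")
    return round_half_away(100.0 * count / universe, decimals)
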