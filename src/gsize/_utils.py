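"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_away(value: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero (not banker's rounding).

    ``ndigits`` may be negative (round to tens, hundreds, ...).
    """
    quantum = Decimal(1).scaleb(-ndigits)
    d = Decimal(repr(float(value))).quantize(quantum, rounding=ROUND_HALF_UP)
    return float(d)


def round_to_nearest(value: float, step: int) -> float:
    """Round to the nearest multiple of ``step`` (ties away from zero)."""
    if step <= 0:
        raise ValueError("step must be positive")
    return round_half_away(value / step) * step
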