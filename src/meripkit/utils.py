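"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (report parity, e.g. 92.485 -> 92.49)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent(k: int, n: int, ndigits: int = 2) -> float:
    """``k / n`` as a percentage rounded half-up; n must be positive."""
    if n <= 0:
        raise ValueError("denominator must be positive")
    return round_half_up(100.0 * k / n, ndigits)
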