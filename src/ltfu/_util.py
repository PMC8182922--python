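"""Small shared helpers."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero, as report tables conventionally do.

    Used only at render time; all internal arithmetic is unrounded.
    """
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def pct(count: int, total: int, ndigits: int = 1) -> float:
    """Percentage of ``count`` in ``total`` rounded half-up to ``ndigits``."""
    if total == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    return round_half_up(100.0 * count / total, ndigits)
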