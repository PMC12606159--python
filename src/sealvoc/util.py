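"""Small shared helpers."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero, at decimal (not binary) precision.

    Printed percentages and resolution figures in this package follow the
    half-up convention (e.g. 16.875 -> 16.9, 8212/23416*100 = 35.07 -> 35.1),
    which differs from Python's banker's rounding for exact ties.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
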