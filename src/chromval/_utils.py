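"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties going away from zero, as analytical reports do.

    Python's built-in ``round`` is banker's rounding; validation tables
    conventionally round half up (2.425 -> 2.43). Goes through ``repr`` so
    binary representation artifacts do not flip ties.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
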