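"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round to `ndigits` decimals with ties going away from zero.

    Report tables use this convention (0.125 -> 0.13, -0.125 -> -0.13);
    Python's built-in banker's rounding would break worked examples built
    from printed two-decimal values.  Goes through ``Decimal(repr(x))`` so
    the decision is made on the shortest decimal representation, not on the
    binary float.
    """
    q = Decimal(1).scaleb(-ndigits)
    d = Decimal(repr(float(x)))
    sign = -1.0 if d < 0 else 1.0
    return sign * float((-d if d < 0 else d).quantize(q, rounding=ROUND_HALF_UP))
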