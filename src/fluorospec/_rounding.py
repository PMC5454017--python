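"""Half-away-from-zero decimal rounding.

Python's built-in ``round`` uses banker's rounding; published tables in this
domain are rounded half-away-from-zero, so reproduction code must use this
helper rather than ``round``.
"""

from decimal import ROUND_HALF_UP, Decimal

__all__ = ["round_half_away"]


def round_half_away(x: float, ndigits: int) -> float:
    """Round ``x`` to ``ndigits`` decimals, ties going away from zero.

    >>> round_half_away(2.675, 2)
    2.68
    >>> round_half_away(-0.5, 0)
    -1.0
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
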