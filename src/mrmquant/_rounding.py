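"""Reporting-precision helpers.

Bioanalytical reports round half-away-from-zero (so 0.1955 -> 0.196, -0.1955
-> -0.196), which differs from Python's built-in banker's rounding.  All
user-facing tables in this package go through these two helpers.
"""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round to ``ndigits`` decimals, ties away from zero."""
    if not math.isfinite(x):
        return x
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(quantum, rounding=ROUND_HALF_UP))


def round_sigfig(x: float, sig: int = 3) -> float:
    """Round to ``sig`` significant figures, ties away from zero."""
    if x == 0 or not math.isfinite(x):
        return x
    exponent = math.floor(math.log10(abs(x)))
    return round_half_away(x, sig - 1 - exponent)
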