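"""Reporting-precision helpers.

Published quantitation tables round half away from zero (0.8375 prints as
0.838).  Binary floats accumulate representation error just below such
midpoints (sum([0.832, 0.836, 0.838, 0.841, 0.840, 0.838]) / 6 evaluates
to 0.8374999...), so reported values are nudged away from zero by a
relative guard of 1e-9 before quantizing.  The guard is far below every
reported precision and only matters within 1e-9 of a rounding midpoint.
"""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal

_GUARD = 1e-9


def round_half_up(x: float, ndigits: int) -> float:
    """Round half away from zero at ``ndigits`` decimals, with a float guard."""
    x = float(x)
    if not math.isfinite(x):
        return x
    guarded = x + math.copysign(abs(x) * _GUARD, x)
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(guarded)).quantize(quantum, rounding=ROUND_HALF_UP))
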