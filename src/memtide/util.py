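"""Small shared helpers."""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal

__all__ = ["round_sig"]


def round_sig(x: float, sig_figs: int) -> float:
    """Round half-up to a number of significant figures.

    Used when comparing computed quantities to values printed at limited
    precision (banker's rounding would round 0.0925 down to 0.092).
    """
    if x == 0 or not math.isfinite(x):
        return x
    d = Decimal(repr(x))
    exp = math.floor(math.log10(abs(x)))
    quant = Decimal(1).scaleb(exp - sig_figs + 1)
    return float(d.quantize(quant, rounding=ROUND_HALF_UP))
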