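"""Report-style rounding: half-up decimals and significant figures.

Internal computation is always full double precision; these helpers exist
only for rendering values the way reference tables print them (indices to
2 d.p., hazard quotients to 5 d.p., cancer risk to 2 significant figures).
"""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal

__all__ = ["round_dp", "round_sig"]


def round_dp(x: float, dp: int) -> float:
    """Round half-up to ``dp`` decimal places."""
    q = Decimal(1).scaleb(-dp)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def round_sig(x: float, sig: int) -> float:
    """Round half-up to ``sig`` significant figures (0 stays 0)."""
    if x == 0 or not math.isfinite(x):
        return x
    dp = sig - 1 - math.floor(math.log10(abs(x)))
    return round_dp(x, dp) if dp >= 0 else float(
        Decimal(repr(x)).quantize(Decimal(1).scaleb(-dp), rounding=ROUND_HALF_UP)
    )
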