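"""Small shared helpers (percentage rounding)."""

from __future__ import annotations

import math
from decimal import ROUND_DOWN, ROUND_HALF_UP, Decimal


def percent_half_up(count: int | float, total: int | float, decimals: int = 1) -> float:
    """100*count/total rounded half-up (not banker's) to ``decimals`` places."""
    if total == 0:
        return math.nan
    q = Decimal(1).scaleb(-decimals)
    return float(
        (Decimal(count) / Decimal(total) * 100).quantize(q, rounding=ROUND_HALF_UP)
    )


def percent_truncated(count: int | float, total: int | float, decimals: int = 1) -> float:
    """100*count/total truncated (rounded toward zero) to ``decimals`` places."""
    if total == 0:
        return math.nan
    q = Decimal(1).scaleb(-decimals)
    return float(
        (Decimal(count) / Decimal(total) * 100).quantize(q, rounding=ROUND_DOWN)
    )
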