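"""Small shared helpers."""
from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, as printed tables conventionally do.

    Python's built-in ``round`` uses banker's rounding, which would turn
    e.g. 0.305 into 0.30 or 0.31 depending on the binary representation;
    reported ratios and percentages here always round half up.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
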