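"""Small shared helpers."""
from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round with ties away from zero (half-up), as printed tables do.

    Python's builtin round() is banker's rounding, which disagrees with the
    conventions used in the reference tables (e.g. 98.185 -> 98.19).
    """
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
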