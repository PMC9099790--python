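"""Small shared helpers."""

from __future__ import annotations

import decimal

__all__ = ["round_half_away"]


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round ``x`` to ``ndigits`` decimals with ties going away from zero.

    Printed tables in the corrosion literature use conventional
    half-away-from-zero rounding, whereas Python's built-in ``round``
    uses banker's rounding; comparisons against printed values go
    through this helper.
    """
    q = decimal.Decimal(1).scaleb(-ndigits)
    return float(decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP))
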