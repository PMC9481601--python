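"""Small numeric helpers shared across modules."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round half away from zero at ``ndigits`` decimals.

    Display tables in pharmacoepidemiology round half-up, not banker's, so
    2.985 -> 2.99 at two decimals.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
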