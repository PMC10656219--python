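"""Small shared numeric helpers."""

from __future__ import annotations

import decimal


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero at the given decimal place.

    Report tables round percentages "half up" (46.27 -> 46, 86.67 -> 87),
    unlike Python's builtin banker's rounding.
    """
    q = decimal.Decimal(1).scaleb(-ndigits)
    out = decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP)
    return float(out) if ndigits > 0 else float(int(out))


def round_half_even(x: float, ndigits: int = 0) -> float:
    q = decimal.Decimal(1).scaleb(-ndigits)
    out = decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_EVEN)
    return float(out) if ndigits > 0 else float(int(out))


ROUNDING = {"half-up": round_half_up, "half-even": round_half_even}
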