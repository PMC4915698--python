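"""Small shared numeric helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

__all__ = ["round_half_up"]


def round_half_up(x: float, decimals: int) -> float:
    """Round half away from zero at ``decimals`` places (ties go up).

    Python's builtin ``round`` is banker's rounding; reported percentages
    and densities use conventional half-up rounding instead.
    """
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
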