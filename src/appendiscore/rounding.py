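"""Decimal rounding dialects for matching printed summary statistics.

Published diagnostic-accuracy tables print percentages to one decimal and
likelihood ratios to two, but rarely state whether values were rounded
half-up, half-even (banker's), or simply truncated.  When auditing such a
table the dialect matters at the margin (86.36 prints as 86.4 half-up but
86.3 truncated), so every dialect is exposed explicitly and the audit
engine reports all of them rather than guessing the authors' intent.
"""

from __future__ import annotations

from decimal import ROUND_DOWN, ROUND_HALF_EVEN, ROUND_HALF_UP, Decimal

__all__ = ["round_half_up", "round_half_even", "truncate", "ROUNDERS", "printed_decimals"]


def _quantize(x: float, ndigits: int, mode: str) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=mode))


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero at `ndigits` decimals (the convention
    most clinical papers use, and the default dialect everywhere here)."""
    return _quantize(x, ndigits, ROUND_HALF_UP)


def round_half_even(x: float, ndigits: int = 0) -> float:
    """IEEE banker's rounding, for sensitivity analysis of an audit."""
    return _quantize(x, ndigits, ROUND_HALF_EVEN)


def truncate(x: float, ndigits: int = 0) -> float:
    """Drop digits beyond `ndigits` without rounding."""
    return _quantize(x, ndigits, ROUND_DOWN)


ROUNDERS = {
    "half_up": round_half_up,
    "half_even": round_half_even,
    "truncate": truncate,
}


def printed_decimals(text: str) -> int:
    """Number of decimal places a printed value carries ("25" -> 0,
    "33.3" -> 1, "78.03" -> 2)."""
    text = text.strip()
    if "." not in text:
        return 0
    return len(text.split(".", 1)[1])
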