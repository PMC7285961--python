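"""Exact percentage rounding shared across reporting modules.

Percentages are reported to one decimal place, rounding halves away from
zero, computed in integer arithmetic so no binary floating-point artifact
can flip the final digit (e.g. 24/225 -> 10.7, 49/225 -> 21.8).
"""

from __future__ import annotations

from fractions import Fraction

__all__ = ["percent_1dp", "round_half_away"]


def round_half_away(value: Fraction, decimals: int = 1) -> float:
    """Round an exact rational to ``decimals`` places, halves away from zero."""
    scale = 10**decimals
    scaled = value * scale
    sign = -1 if scaled < 0 else 1
    scaled = abs(scaled)
    q, r = divmod(scaled.numerator, scaled.denominator)
    if 2 * r >= scaled.denominator:
        q += 1
    return sign * q / scale


def percent_1dp(numerator: int, denominator: int) -> float:
    """``100 * numerator / denominator`` rounded to one decimal, half away from zero."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return round_half_away(Fraction(100 * numerator, denominator), 1)
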