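"""Percentage formatting conventions used by the table-rendering operations.

Genome description tables in the taxono-genomics literature truncate
percentages to two decimals (135/2,003 prints as 6.73, not 6.74); the G+C
percentage alone is conventionally rounded to one decimal. Both behaviours
are provided explicitly so each table states which one it uses.
"""

from __future__ import annotations

from decimal import ROUND_DOWN, ROUND_HALF_UP, Decimal

__all__ = ["truncate_percent", "truncate", "round_percent_1dp"]


def truncate_percent(numerator: int | float, denominator: int | float, decimals: int = 2) -> float:
    """100 * numerator / denominator, truncated (not rounded) to `decimals`.

    Exact for integer inputs: computed in decimal arithmetic so that e.g.
    truncate_percent(135, 2003) == 6.73.
    """
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    q = Decimal(100) * Decimal(str(numerator)) / Decimal(str(denominator))
    return float(q.quantize(Decimal(1).scaleb(-decimals), rounding=ROUND_DOWN))


def truncate(x: float, decimals: int = 2) -> float:
    """Truncate a value toward zero to `decimals` decimal places."""
    return float(Decimal(str(x)).quantize(Decimal(1).scaleb(-decimals), rounding=ROUND_DOWN))


def round_percent_1dp(numerator: int | float, denominator: int | float) -> float:
    """100 * numerator / denominator rounded half-up to one decimal (G+C convention)."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    q = Decimal(100) * Decimal(str(numerator)) / Decimal(str(denominator))
    return float(q.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
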