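"""Centralized rounding rules for reported percentages.

All user-facing percentages in this package round half-up (0.005 -> 0.01),
not banker's rounding, so printed compliance and satisfaction figures are
stable and match the conventional clinical-report style.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round ``x`` to ``ndigits`` decimals with ties going away from zero-ward up."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent(numerator: int, denominator: int, ndigits: int = 2) -> float:
    """100 * numerator / denominator, rounded half-up to ``ndigits`` decimals.

    Raises ``ZeroDivisionError`` for a zero denominator: callers decide how a
    degenerate cell is reported (usually excluded, never silently 0).
    """
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    # Exact rational -> Decimal division avoids float artifacts near ties.
    value = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    q = Decimal(1).scaleb(-ndigits)
    return float(value.quantize(q, rounding=ROUND_HALF_UP))
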