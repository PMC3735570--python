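"""Small shared helpers."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP


def pct(count: float, total: float, decimals: int = 2) -> float:
    """Percentage ``100 * count / total`` rounded half-up to ``decimals``.

    Half-up rounding mirrors how summary tables in the resistance-gene
    literature are typically formatted (e.g. 24/355 -> 6.76).
    """
    if total == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    q = Decimal(1).scaleb(-decimals)
    return float(
        (Decimal(100) * Decimal(str(count)) / Decimal(str(total))).quantize(
            q, rounding=ROUND_HALF_UP
        )
    )
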