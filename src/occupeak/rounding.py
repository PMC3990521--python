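"""Half-up percentage rounding used in all rendered summary tables."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round half away from zero at the given number of decimals (35.5 -> 36)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent(count: float, total: float, decimals: int = 0) -> float:
    """100*count/total rounded half-up to `decimals` places."""
    if total == 0:
        raise ZeroDivisionError("percentage of an empty total")
    return round_half_up(100.0 * count / total, decimals)


def format_count_pct(count: int, total: int, decimals: int = 0) -> str:
    """Render "6,398 (36%)"-style cells with thousands separators."""
    pct = percent(count, total, decimals) if total else 0.0
    if decimals == 0:
        return f"{count:,} ({pct:.0f}%)"
    return f"{count:,} ({pct:.{decimals}f}%)"
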