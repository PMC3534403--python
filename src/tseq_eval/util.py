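"""Small shared helpers: report rounding and percentage formatting."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (half-up), as report tables print.

    Python's builtin ``round`` is banker's rounding; report percentages use
    conventional half-up at one decimal.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def fmt_pct(x: float | None) -> str:
    """Format a percentage for TSV output: one decimal, 'NA' when undefined."""
    if x is None:
        return "NA"
    return f"{round_half_up(x, 1):.1f}"
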