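"""Reporting-precision rounding.

Summary tables print percentages as whole numbers and ratios, folds and
per-plant means to one decimal.  Exact halves round toward zero
(truncation-style reporting, so e.g. 2.125 prints as 2.1), which is what
the published bookkeeping uses; everything else rounds to nearest.
"""

from decimal import ROUND_HALF_DOWN, Decimal

__all__ = ["report_round", "report_percent"]


def report_round(x: float, ndigits: int = 1) -> float:
    """Round ``x`` to ``ndigits`` decimals, ties toward zero."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_DOWN))


def report_percent(fraction: float) -> int:
    """Express a fraction as a whole percentage."""
    return int(report_round(100.0 * fraction, 0))
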