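"""Small shared helpers (reporting-precision rounding, significance stars)."""

from decimal import ROUND_HALF_UP, Decimal

__all__ = ["round_half_up", "significance_stars"]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round ``x`` to ``ndigits`` decimals, halves away from zero.

    Operates on the shortest decimal representation of the binary float
    (``repr``), so a value stored as 2.049999... rounds down to 2.0 while a
    genuine 2.05 rounds up.  This is the convention used for every reported
    percentage and 1-decimal RMSD/EF in the summary tables.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def significance_stars(p: float, alpha: tuple[float, float] = (0.05, 0.01)) -> str:
    """'**' for p < alpha[1], '*' for p < alpha[0], else ''."""
    if p < alpha[1]:
        return "**"
    if p < alpha[0]:
        return "*"
    return ""
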