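"""Small shared helpers."""

from decimal import ROUND_HALF_UP, Decimal


def round_half_away(value: float, ndigits: int) -> float:
    """Round to ``ndigits`` decimals with ties going away from zero.

    Python's built-in ``round`` is banker's rounding; score reports use
    the conventional half-away-from-zero rule instead so printed cutoffs
    are reproducible.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))
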