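from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero (half-up), as in printed report tables.

    Python's built-in ``round`` is banker's rounding; report-style percentages
    such as 90.645 -> 90.65 need half-up. Goes through ``Decimal(str(x))`` so
    the decision is made on the shortest decimal representation of ``x``.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(str(x)).quantize(q, rounding=ROUND_HALF_UP))
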