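"""Small shared numeric helpers."""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero (commercial rounding).

    Percentages printed by the toolkit use this convention so that, e.g.,
    26/28 = 92.857...% prints as 93%.  Python's built-in ``round`` uses
    banker's rounding and would disagree on exact .5 ties.
    """
    q = Decimal(1).scaleb(-ndigits)
    d = Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP)
    return float(d)


def percent(numerator: float, denominator: float, ndigits: int = 0) -> float:
    """Round-half-up percentage of a fraction; integer percent by default."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    return round_half_up(100.0 * numerator / denominator, ndigits)


def mean_sem(values: Sequence[float]) -> tuple[float, float]:
    """Arithmetic mean and standard error of the mean (n-1 denominator).

    SEM is NaN for a single observation.
    """
    vals = [v for v in values]
    n = len(vals)
    if n == 0:
        raise ValueError("mean_sem of empty sequence")
    m = sum(vals) / n
    if n == 1:
        return m, float("nan")
    var = sum((v - m) ** 2 for v in vals) / (n - 1)
    return m, math.sqrt(var) / math.sqrt(n)


def drop_none(values: Iterable[Optional[float]]) -> list[float]:
    return [v for v in values if v is not None]
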