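"""Two-state amide exchange kinetics.

A structured amide exchanges through transient local opening,

    closed  <-- k_cl / k_op -->  open  -- k_int -->  exchanged,

giving the observed rate k_obs = k_int*k_op / (k_int + k_op + k_cl).
Under native conditions (k_cl >> k_op) two limits are distinguished:
EX1 (k_int >> k_cl, exchange on every opening, k_obs -> k_op) and EX2
(k_cl >> k_int, many openings per exchange, k_obs -> k_int/P with the
protection factor P = k_cl/k_op).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["TwoStateRates", "k_obs", "classify_regime", "protection_from_rates"]


@dataclass(frozen=True)
class TwoStateRates:
    """Opening, closing and intrinsic rates, all in 1/s and non-negative."""

    k_op: float
    k_cl: float
    k_int: float

    def __post_init__(self) -> None:
        if min(self.k_op, self.k_cl, self.k_int) < 0:
            raise ValueError("rates must be non-negative")


def k_obs(rates: TwoStateRates) -> float:
    """Observed exchange rate of the two-state scheme (1/s)."""
    denom = rates.k_int + rates.k_op + rates.k_cl
    if denom == 0:
        raise ZeroDivisionError("k_obs undefined: all rates are zero")
    return rates.k_int * rates.k_op / denom


def classify_regime(rates: TwoStateRates, ratio_threshold: float = 10.0) -> str:
    """'EX2' when closing outpaces intrinsic exchange by the threshold,
    'EX1' for the converse, else 'intermediate'.  The threshold is a
    convention: the limits are defined only asymptotically."""
    if rates.k_int > 0 and rates.k_cl / rates.k_int >= ratio_threshold:
        return "EX2"
    if rates.k_cl > 0 and rates.k_int / rates.k_cl >= ratio_threshold:
        return "EX1"
    if rates.k_cl == 0 and rates.k_int > 0:
        return "EX1"
    if rates.k_int == 0 and rates.k_cl > 0:
        return "EX2"
    return "intermediate"


def protection_from_rates(k_op: float, k_cl: float) -> float:
    """Protection factor P = k_cl/k_op; infinite when opening never occurs."""
    if k_op < 0 or k_cl < 0:
        raise ValueError("rates must be non-negative")
    if k_op == 0:
        return math.inf
    return k_cl / k_op
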