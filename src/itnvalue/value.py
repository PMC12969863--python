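"""Equivalent annual cost (EAC) and willingness-to-pay for longer-lived nets.

A net bought at price P and kept for b years is an investment whose cost is
spread over its life with the standard annuitization

    EAC = P * r / (1 - (1 + r)^-b)

at annual discount rate r (the r -> 0 limit is P / b).  Dividing by the
number of people sleeping under the net gives EAC per person-year of
protection, the value-for-money metric.

A longer-retained net (l years instead of b) has the same EAC when its price
is scaled by the ratio of annuity factors

    a = (1 - (1 + r)^-l) / (1 - (1 + r)^-b)

so P_l = a * P is the threshold price — the most a rational buyer should be
willing to pay for the longer-lived product — and P_l - P is the premium
(marginal willingness-to-pay) for the extra retention.  Two policy scenarios
are modelled: retention raised to exactly 3 years, and retention extended by
6 months over the country baseline.

All functions are numpy-vectorized; scalars in, scalars out.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Scenario",
    "WtpResult",
    "equivalent_annual_cost",
    "eac_per_person",
    "relative_price_increase",
    "threshold_price",
    "premium",
    "scenario_retention",
    "wtp",
]

#: Discount rates below this are treated as exactly zero (analytic limit).
_ZERO_RATE = 1e-12

#: Retention target (years) of the first policy scenario.
THREE_YEARS = 3.0
#: Retention extension (years) of the second policy scenario.
SIX_MONTHS = 0.5


class Scenario(str, enum.Enum):
    TO_THREE_YEARS = "three_years"
    PLUS_SIX_MONTHS = "plus_6m"


def _annuity_factor(rate, years):
    """(1 - (1+r)^-b) / r, with the r -> 0 limit b."""
    rate = np.asarray(rate, dtype=float)
    years = np.asarray(years, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        factor = (1.0 - (1.0 + rate) ** (-years)) / rate
    return np.where(rate < _ZERO_RATE, years, factor)


def equivalent_annual_cost(price, rate, retention):
    """EAC in USD per year: ``P*r / (1 - (1+r)^-b)``, or ``P/b`` at r = 0."""
    price = np.asarray(price, dtype=float)
    rate = np.asarray(rate, dtype=float)
    retention = np.asarray(retention, dtype=float)
    if np.any(price <= 0):
        raise ValueError("price must be positive")
    if np.any(retention <= 0):
        raise ValueError("retention must be positive")
    if np.any(rate < 0):
        raise ValueError("discount rate must be >= 0")
    out = price / _annuity_factor(rate, retention)
    return out if out.ndim else float(out)


def eac_per_person(eac, persons_per_net):
    """EAC divided by the number of people protected per net."""
    eac = np.asarray(eac, dtype=float)
    persons = np.asarray(persons_per_net, dtype=float)
    if np.any(persons < 1):
        raise ValueError("persons_per_net must be >= 1")
    out = eac / persons
    return out if out.ndim else float(out)


def relative_price_increase(rate, retention_l, retention_b):
    """Annuity-factor ratio ``a``; the price multiplier equating EACs.

    ``a > 1`` iff ``l > b``; at r = 0 this is the intuitive ``l / b``.
    """
    rate = np.asarray(rate, dtype=float)
    longer = np.asarray(retention_l, dtype=float)
    base = np.asarray(retention_b, dtype=float)
    if np.any(longer <= 0) or np.any(base <= 0):
        raise ValueError("retention times must be positive")
    if np.any(rate < 0):
        raise ValueError("discount rate must be >= 0")
    out = _annuity_factor(rate, longer) / _annuity_factor(rate, base)
    return out if out.ndim else float(out)


def threshold_price(price, a):
    """Threshold price ``P_l = a * P`` of the longer-retained net."""
    price = np.asarray(price, dtype=float)
    if np.any(price <= 0):
        raise ValueError("price must be positive")
    out = price * np.asarray(a, dtype=float)
    return out if out.ndim else float(out)


def premium(price_l, price):
    """Marginal willingness-to-pay ``P_l - P`` (negative when l < b)."""
    out = np.asarray(price_l, dtype=float) - np.asarray(price, dtype=float)
    return out if out.ndim else float(out)


def scenario_retention(retention_b, scenario: Scenario):
    """Target retention l for a policy scenario."""
    scenario = Scenario(scenario)
    base = np.asarray(retention_b, dtype=float)
    if np.any(base <= 0):
        raise ValueError("retention must be positive")
    if scenario is Scenario.TO_THREE_YEARS:
        out = np.full_like(base, THREE_YEARS)
    else:
        out = base + SIX_MONTHS
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class WtpResult:
    """Deterministic willingness-to-pay outputs for one (price, country) pair."""

    scenario: Scenario
    retention_l: float
    relative_increase_a: float
    threshold_price_Pl: float
    premium: float


def wtp(price, rate, retention_b, scenario: Scenario) -> WtpResult:
    """Full threshold-price calculation for one scenario."""
    long_ret = scenario_retention(retention_b, scenario)
    a = relative_price_increase(rate, long_ret, retention_b)
    p_l = threshold_price(price, a)
    return WtpResult(
        scenario=Scenario(scenario),
        retention_l=float(np.asarray(long_ret)),
        relative_increase_a=float(np.asarray(a)),
        threshold_price_Pl=float(np.asarray(p_l)),
        premium=float(np.asarray(p_l) - np.asarray(price, dtype=float)),
    )
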