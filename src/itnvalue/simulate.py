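"""Seeded probabilistic sensitivity analysis for the value-for-money model.

Uncertain inputs — baseline price P, median retention b, persons per net n_p
and the discount rate r — are described by :class:`DistributionSpec`s on each
:class:`CountryProfile`.  Each simulation draws all inputs jointly
(independently across inputs), pushes them through the closed-form value
model, and summarizes the propagated quantity with mean, quartiles and the
5th/95th percentiles (a 90% interval, matching the usual PSA reporting).

Each (country, net class, scenario) combination owns an independent random
stream derived from the master seed by a stable hash, so adding countries or
scenarios never perturbs existing results.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import value
from .records import CountryProfile, DistKind, DistributionSpec
from .value import Scenario

logger = logging.getLogger("itnvalue")

__all__ = [
    "SimulationSummary",
    "WtpSimulation",
    "sample",
    "stream_rng",
    "simulate_eac_per_person",
    "simulate_wtp",
    "run_country_simulations",
]


@dataclass(frozen=True)
class SimulationSummary:
    """Distribution summary of one propagated quantity.

    ``p05``/``p95`` bound the central 90% interval; ``q25``/``q75`` the
    inter-quartile range.  Percentiles use numpy's linear-interpolation
    convention so outputs are portable across platforms.
    """

    n_iterations: int
    mean: float
    q25: float
    median: float
    q75: float
    p05: float
    p95: float

    def __post_init__(self) -> None:
        if not (self.p05 <= self.q25 <= self.median <= self.q75 <= self.p95):
            raise ValueError("summary percentiles out of order")

    @classmethod
    def from_samples(cls, x: np.ndarray) -> "SimulationSummary":
        x = np.asarray(x, dtype=float)
        p05, q25, med, q75, p95 = np.percentile(x, [5, 25, 50, 75, 95])
        # degenerate sample: report the value itself, exactly (summation
        # order must not perturb a constant)
        mean = float(x[0]) if np.all(x == x[0]) else float(np.mean(x))
        return cls(
            n_iterations=int(x.size),
            mean=mean,
            q25=float(q25),
            median=float(med),
            q75=float(q75),
            p05=float(p05),
            p95=float(p95),
        )


@dataclass(frozen=True)
class WtpSimulation:
    """Summaries of the three willingness-to-pay outputs."""

    scenario: Scenario
    relative_increase_a: SimulationSummary
    threshold_price: SimulationSummary
    premium: SimulationSummary


def sample(spec: DistributionSpec, n: int, seed) -> np.ndarray:
    """Draw ``n`` values from a distribution spec; deterministic per seed.

    ``seed`` may be an int or a ``numpy.random.Generator``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = spec.params
    if spec.kind is DistKind.POINT:
        return np.full(n, p[0], dtype=float)
    if spec.kind is DistKind.UNIFORM:
        return rng.uniform(p[0], p[1], size=n)
    if spec.kind is DistKind.TRIANGULAR:
        return rng.triangular(p[0], p[1], p[2], size=n)
    if spec.kind is DistKind.PERT:
        lo, mode, hi = p
        # standard beta-PERT with shape parameter 4
        alpha = 1.0 + 4.0 * (mode - lo) / (hi - lo)
        beta = 1.0 + 4.0 * (hi - mode) / (hi - lo)
        return lo + (hi - lo) * rng.beta(alpha, beta, size=n)
    if spec.kind is DistKind.NORMAL_TRUNCATED:
        mu, sigma, lo, hi = p
        # inverse-CDF sampling keeps the draw count exactly n
        from scipy.stats import truncnorm

        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        u = rng.uniform(0.0, 1.0, size=n)
        return truncnorm.ppf(u, a, b, loc=mu, scale=sigma)
    return rng.gamma(shape=p[0], scale=p[1], size=n)


def stream_rng(master_seed: int, *labels: str) -> np.random.Generator:
    """Independent generator for a labelled stream under one master seed.

    The labels are hashed (SHA-256) into the seed sequence, so each
    (country, net class, scenario) stream is stable regardless of how many
    other streams are drawn.
    """
    digest = hashlib.sha256("\x1f".join(labels).encode()).digest()
    key = int.from_bytes(digest[:8], "big")
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), key]))


def _draw_inputs(profile: CountryProfile, net_class: str, specs, n_iter, rng):
    """Joint draw with rejection of invariant-violating values.

    Any iteration whose draw violates the value-model preconditions
    (non-positive price or retention, persons per net below 1, negative
    rate) is redrawn; the rejection count is logged.
    """
    draws = [sample(s, n_iter, rng) for s in specs]
    rejected = 0
    for _ in range(100):
        bad = _invalid_mask(draws)
        n_bad = int(bad.sum())
        if n_bad == 0:
            break
        rejected += n_bad
        for i, s in enumerate(specs):
            draws[i][bad] = sample(s, n_bad, rng)
    else:
        raise RuntimeError("rejection sampling did not converge in 100 rounds")
    if rejected:
        logger.info(
            "simulate %s/%s: %d draws rejected and redrawn",
            profile.country,
            net_class,
            rejected,
        )
    return draws


def _invalid_mask(draws):
    price, retention, persons, rate = draws
    return (price <= 0) | (retention <= 0) | (persons < 1) | (rate < 0)


def _specs(profile: CountryProfile, net_class: str):
    try:
        price_spec = profile.price_by_class[net_class]
    except KeyError:
        raise KeyError(
            f"profile {profile.country!r} has no price spec for net class {net_class!r}"
        ) from None
    return (
        price_spec,
        profile.retention_spec(),
        profile.persons_per_net,
        DistributionSpec.point(profile.discount_rate_r),
    )


def simulate_eac_per_person(
    profile: CountryProfile, net_class: str, n_iter: int, seed: int
) -> SimulationSummary:
    """Monte Carlo EAC per person protected for one country and net class."""
    rng = stream_rng(seed, profile.country, net_class, "eac")
    price, retention, persons, rate = _draw_inputs(
        profile, net_class, _specs(profile, net_class), n_iter, rng
    )
    eac = value.equivalent_annual_cost(price, rate, retention)
    per_person = value.eac_per_person(eac, persons)
    return SimulationSummary.from_samples(per_person)


def simulate_wtp(
    profile: CountryProfile,
    net_class: str,
    scenario: Scenario,
    n_iter: int,
    seed: int,
) -> WtpSimulation:
    """Monte Carlo threshold price and premium for one scenario."""
    scenario = Scenario(scenario)
    rng = stream_rng(seed, profile.country, net_class, scenario.value)
    price, retention, _persons, rate = _draw_inputs(
        profile, net_class, _specs(profile, net_class), n_iter, rng
    )
    longer = value.scenario_retention(retention, scenario)
    a = value.relative_price_increase(rate, longer, retention)
    p_l = value.threshold_price(price, a)
    prem = p_l - price
    return WtpSimulation(
        scenario=scenario,
        relative_increase_a=SimulationSummary.from_samples(a),
        threshold_price=SimulationSummary.from_samples(p_l),
        premium=SimulationSummary.from_samples(prem),
    )


def run_country_simulations(
    profiles,
    n_iter: int,
    seed: int,
    net_classes=None,
    scenarios=(Scenario.TO_THREE_YEARS, Scenario.PLUS_SIX_MONTHS),
) -> pd.DataFrame:
    """Long-format simulation table across countries, classes and scenarios.

    One row per (country, net_class, quantity, scenario); quantities are
    ``eac_per_person`` (scenario blank) and the three WTP outputs.
    """
    rows = []

    def add(country, net_class, quantity, scenario, s: SimulationSummary):
        rows.append(
            {
                "country": country,
                "net_class": net_class,
                "quantity": quantity,
                "scenario": scenario,
                "n": s.n_iterations,
                "mean": s.mean,
                "p05": s.p05,
                "q25": s.q25,
                "median": s.median,
                "q75": s.q75,
                "p95": s.p95,
            }
        )

    for profile in profiles:
        classes = net_classes or sorted(profile.price_by_class)
        for net_class in classes:
            add(
                profile.country,
                net_class,
                "eac_per_person",
                "",
                simulate_eac_per_person(profile, net_class, n_iter, seed),
            )
            for scenario in scenarios:
                res = simulate_wtp(profile, net_class, scenario, n_iter, seed)
                add(profile.country, net_class, "a", scenario.value, res.relative_increase_a)
                add(profile.country, net_class, "threshold_price", scenario.value, res.threshold_price)
                add(profile.country, net_class, "premium", scenario.value, res.premium)
    return pd.DataFrame(rows)
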