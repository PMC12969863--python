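"""Synthetic ITN market data with the statistical structure the analysis assumes.

Real ITN transaction databases are proprietary, so every downstream stage is
exercised on generated data instead.  The generator is explicit about its
data-generating process, which mirrors the assumptions of the price model:

- each year has a set of named suppliers whose target market shares follow
  linear trajectories (the remainder is shipped by unknown suppliers), so
  the market can move from monopoly toward moderate concentration;
- each transaction's expected real price is ``exp(x·β)`` where ``x`` is the
  exact design row :func:`itnvalue.price_model.build_design` would produce
  for it, and β is a configurable "truth" vector whose defaults are
  realistic log-scale effects (PBO premium ≈ +34%, a negative market-shaping
  regime effect, oil pass-through reversing under the regime, ...);
- the concentration→price link uses the previous year's *realized* HHI of
  the generated shipments, so fitting the model on its own output is an
  end-to-end consistency check;
- realized prices are gamma-distributed around their mean with a configured
  shape (``None`` means no noise: prices equal their means exactly);
- brands are nested within suppliers and carry a small normal log-scale
  intercept, giving the price model's brand adjustment something to absorb.

Country profiles for the value model get retention medians spread over
roughly 1–3.5 years (the observed span of median net retention across
African countries), baseline prices near late-period market prices, 1–4
persons protected per net, and a 3% discount rate.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .price_model import FINAL_TERMS, ModelSpec, build_design
from .records import (
    UNKNOWN_SUPPLIER,
    CountryProfile,
    DistributionSpec,
    FibreType,
    NetType,
    Region,
    TransactionRecord,
)

__all__ = [
    "SupplierTrajectory",
    "MarketScenarioConfig",
    "CountryScenarioConfig",
    "ConfigError",
    "generate_transactions",
    "generate_country_profiles",
    "DEFAULT_TRUTH",
]


class ConfigError(ValueError):
    """A scenario configuration is internally inconsistent."""


@dataclass(frozen=True)
class SupplierTrajectory:
    """Target market share moving linearly from the first to the last year."""

    label: str
    share_start: float
    share_end: float

    def share(self, year: int, first: int, last: int) -> float:
        if last == first:
            return self.share_start
        t = (year - first) / (last - first)
        return max(0.0, (1.0 - t) * self.share_start + t * self.share_end)


#: Market moves from single-supplier toward six suppliers plus a small
#: unknown-supplier remainder — monopoly decaying to moderate concentration.
DEFAULT_SUPPLIERS = (
    SupplierTrajectory("VestergaardCo", 1.00, 0.22),
    SupplierTrajectory("SumiCo", 0.00, 0.20),
    SupplierTrajectory("TanaCo", 0.00, 0.17),
    SupplierTrajectory("BasfCo", 0.00, 0.14),
    SupplierTrajectory("DctCo", 0.00, 0.10),
    SupplierTrajectory("MoskitoCo", 0.00, 0.07),
)

#: True log-scale effects used by default.  Values are the kind of effects
#: the fitted model is expected to see on real procurement data: product
#: premiums for PBO/dual-AI nets, a positive area and concentration effect,
#: a strong negative market-shaping regime effect, and oil pass-through
#: that reverses sign under the regime.
DEFAULT_TRUTH: Mapping[str, float] = {
    "intercept": -0.552,
    "net_type[DUAL_AI]": 0.214,
    "net_type[PBO]": 0.293,
    "area_m2": 0.042,
    "nets_shipped_millions": -0.001,
    "hhi_thousands": 0.253,
    "gfmss": -0.738,
    "oil_tens:gfmss[present]": -0.042,
    "oil_tens:gfmss[absent]": 0.061,
    "region[ASIA_PACIFIC]:gfmss[present]": 0.057,
    "region[EECA]:gfmss[present]": -0.015,
    "region[LAC]:gfmss[present]": 0.043,
    "region[MENA]:gfmss[present]": -0.018,
    "region[ASIA_PACIFIC]:gfmss[absent]": -0.065,
    "region[EECA]:gfmss[absent]": -0.005,
    "region[LAC]:gfmss[absent]": 0.088,
    "region[MENA]:gfmss[absent]": 0.043,
    "nets_shipped_millions:gfmss[present]": 0.003,
}

_BUYERS = ("GLOBAL_FUND", "PMI", "UNICEF", "AMF")
_BUYER_WEIGHTS = (0.55, 0.25, 0.12, 0.08)


@dataclass(frozen=True)
class MarketScenarioConfig:
    """Everything that defines a synthetic transaction table."""

    years: tuple[int, int] = (2004, 2021)
    suppliers: tuple[SupplierTrajectory, ...] = DEFAULT_SUPPLIERS
    n_transactions_per_year: int = 300
    glm_truth: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_TRUTH))
    gamma_shape: float | None = 25.0  # None: noiseless (prices = their means)
    gfmss_start_year: int = 2016
    hhi_lag: int = 1
    brand_sd: float = 0.1
    brands_per_supplier: int = 2
    area_range: tuple[float, float] = (10.0, 25.0)
    oil_range: tuple[float, float] = (20.0, 110.0)
    market_size_range_millions: tuple[float, float] = (50.0, 250.0)
    region_weights: Mapping[Region, float] = field(
        default_factory=lambda: {
            Region.SSA: 0.80,
            Region.ASIA_PACIFIC: 0.10,
            Region.EECA: 0.03,
            Region.LAC: 0.05,
            Region.MENA: 0.02,
        }
    )
    net_type_weights: Mapping[NetType, float] = field(
        default_factory=lambda: {
            NetType.PYRETHROID: 0.70,
            NetType.PBO: 0.20,
            NetType.DUAL_AI: 0.10,
        }
    )
    fibre_weights: Mapping[FibreType, float] = field(
        default_factory=lambda: {FibreType.POLYESTER: 0.5, FibreType.POLYETHYLENE: 0.5}
    )
    seed: int = 0

    def year_list(self) -> list[int]:
        return list(range(self.years[0], self.years[1] + 1))

    def shares_for_year(self, year: int) -> dict[str, float]:
        first, last = self.years
        shares = {s.label: s.share(year, first, last) for s in self.suppliers}
        total = sum(shares.values())
        if total > 1.0 + 1e-9:
            raise ConfigError(
                f"supplier share trajectories sum to {total:.4f} > 1 in {year}"
            )
        return shares


def _weighted_choice(rng, values, weights, size):
    w = np.asarray(list(weights), dtype=float)
    return rng.choice(len(values), size=size, p=w / w.sum())


def generate_transactions(
    config: MarketScenarioConfig | None = None, seed: int | None = None
) -> list[TransactionRecord]:
    """Generate a transaction table; byte-identical for a fixed seed.

    Prices are in base-year USD already (nominal == real), so the table can
    feed the price model directly; a deflator table is only needed when
    exercising the inflation-adjustment step itself.
    """
    config = config or MarketScenarioConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    years = config.year_list()
    labels = [s.label for s in config.suppliers]

    # brand intercepts, nested within supplier, drawn once per scenario
    brand_delta: dict[str, float] = {}
    for sup in labels + [UNKNOWN_SUPPLIER]:
        for k in range(1, config.brands_per_supplier + 1):
            name = f"{sup}-B{k}"
            brand_delta[name] = float(rng.normal(0.0, config.brand_sd)) if config.brand_sd > 0 else 0.0

    region_levels = list(config.region_weights)
    nettype_levels = list(config.net_type_weights)
    fibre_levels = list(config.fibre_weights)

    records: list[TransactionRecord] = []
    for year in years:
        shares = config.shares_for_year(year)
        p_unknown = max(0.0, 1.0 - sum(shares.values()))
        pool = labels + [UNKNOWN_SUPPLIER]
        probs = [shares[s] for s in labels] + [p_unknown]

        n = config.n_transactions_per_year
        oil = float(rng.uniform(*config.oil_range))
        market_size = float(rng.uniform(*config.market_size_range_millions))

        sup_idx = _weighted_choice(rng, pool, probs, n)
        brand_k = rng.integers(1, config.brands_per_supplier + 1, size=n)
        raw = rng.lognormal(mean=0.0, sigma=1.0, size=n)
        qty = np.maximum(1, np.round(raw * market_size * 1e6 / raw.sum())).astype(int)
        area = rng.uniform(*config.area_range, size=n)
        reg_idx = _weighted_choice(rng, region_levels, config.region_weights.values(), n)
        nt_idx = _weighted_choice(rng, nettype_levels, config.net_type_weights.values(), n)
        fb_idx = _weighted_choice(rng, fibre_levels, config.fibre_weights.values(), n)
        buyer_idx = _weighted_choice(rng, _BUYERS, _BUYER_WEIGHTS, n)

        for i in range(n):
            sup = pool[sup_idx[i]]
            records.append(
                TransactionRecord(
                    year=year,
                    supplier=sup,
                    brand=f"{sup}-B{brand_k[i]}",
                    buyer=_BUYERS[buyer_idx[i]],
                    unit_price_nominal=1.0,  # placeholder until the mean is known
                    quantity=int(qty[i]),
                    net_type=nettype_levels[nt_idx[i]],
                    fibre_type=fibre_levels[fb_idx[i]],
                    area_m2=float(area[i]),
                    region=region_levels[reg_idx[i]],
                    oil_price_nominal=oil,
                    unit_price_real=1.0,
                    oil_price_real=oil,
                )
            )

    # the price mean comes from the exact design matrix the model would
    # build for these records, so generation and fitting are consistent
    spec = ModelSpec(
        terms=FINAL_TERMS,
        gfmss_start_year=config.gfmss_start_year,
        brand_mode="omit",
        hhi_lag=config.hhi_lag,
    )
    design = build_design(records, spec)
    unknown_terms = set(config.glm_truth) - set(design.columns)
    if unknown_terms:
        raise ConfigError(f"glm_truth names unknown design columns: {sorted(unknown_terms)}")
    beta = np.array([config.glm_truth.get(c, 0.0) for c in design.columns])
    eta = design.X @ beta + np.array([brand_delta[r.brand] for r in records])
    mu = np.exp(eta)
    if config.gamma_shape is None or np.isinf(config.gamma_shape):
        price = mu
    else:
        if not config.gamma_shape > 0:
            raise ConfigError("gamma_shape must be positive")
        price = rng.gamma(shape=config.gamma_shape, scale=mu / config.gamma_shape)

    return [
        dataclasses.replace(
            r, unit_price_nominal=float(p), unit_price_real=float(p)
        )
        for r, p in zip(records, price)
    ]


# ---------------------------------------------------------------------------
# country profiles


@dataclass(frozen=True)
class CountryScenarioConfig:
    """Defines a set of synthetic country profiles.

    Defaults: 40 countries with median retention spread over 1–3.5 years;
    baseline prices near the late-period market level (pyrethroid ≈ $1.95,
    PBO/dual-AI ≈ $2.67) with 15% in-country spread; 1–4 persons protected
    per net; 3% annual discount rate.
    """

    n_countries: int = 40
    retention_range: tuple[float, float] = (1.0, 3.5)
    price_truth_by_class: Mapping[str, float] = field(
        default_factory=lambda: {"pyrethroid": 1.95, "pbo_dual": 2.67}
    )
    price_cv: float = 0.15
    persons_per_net_range: tuple[float, float] = (1.0, 4.0)
    discount_rate: float = 0.03
    interval_halfwidth_frac: tuple[float, float] = (0.15, 0.35)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.retention_range
        if not 0 < lo <= hi:
            raise ConfigError("retention_range must be positive and ordered")
        lo, hi = self.persons_per_net_range
        if not 1 <= lo <= hi:
            raise ConfigError("persons_per_net_range must be ordered within [1, inf)")


def generate_country_profiles(
    config: CountryScenarioConfig | None = None, seed: int | None = None
) -> list[CountryProfile]:
    """Generate country profiles; deterministic for a fixed seed."""
    config = config or CountryScenarioConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    lo, hi = config.retention_range
    medians = np.sort(rng.uniform(lo, hi, size=config.n_countries))
    profiles = []
    for i, b in enumerate(medians, start=1):
        u_lo, u_hi = rng.uniform(*config.interval_halfwidth_frac, size=2)
        interval = (float(b * (1.0 - u_lo)), float(b * (1.0 + u_hi)))
        price_specs = {
            cls: DistributionSpec.normal_truncated(
                mean, config.price_cv * mean, 0.0, np.inf
            )
            for cls, mean in config.price_truth_by_class.items()
        }
        profiles.append(
            CountryProfile(
                country=f"Country{i:02d}",
                retention_median_b=float(b),
                retention_interval=interval,
                price_by_class=price_specs,
                persons_per_net=DistributionSpec.uniform(*config.persons_per_net_range),
                discount_rate_r=config.discount_rate,
            )
        )
    return profiles
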