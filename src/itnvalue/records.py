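"""Domain types for the ITN market and value-for-money analysis.

The package models the global market for insecticide-treated bednets (ITNs):
individual procurement transactions (price, quantity, product attributes,
market context) and per-country profiles (median net retention time, baseline
prices, persons protected per net, discount rate) that feed the
equivalent-annual-cost and willingness-to-pay calculations.
"""

from __future__ import annotations

import dataclasses
import enum
import math
from dataclasses import dataclass
from typing import Mapping

__all__ = [
    "NetType",
    "FibreType",
    "Region",
    "UNKNOWN_SUPPLIER",
    "TransactionRecord",
    "DeflatorTable",
    "DistKind",
    "DistributionSpec",
    "CountryProfile",
]

#: Reserved supplier label for transactions whose supplier is not recorded.
#: It is a first-class label (not a missing value) so that concentration
#: sensitivity analysis can reason about it explicitly.
UNKNOWN_SUPPLIER = "UNKNOWN"


class NetType(str, enum.Enum):
    """Insecticide class of a bednet.

    PYRETHROID is the original single-insecticide net; PBO nets add the
    piperonyl butoxide synergist; DUAL_AI nets carry two active ingredients.
    UNTREATED nets carry no insecticide and are excluded from price analysis.
    """

    PYRETHROID = "PYRETHROID"
    PBO = "PBO"
    DUAL_AI = "DUAL_AI"
    UNTREATED = "UNTREATED"


class FibreType(str, enum.Enum):
    POLYESTER = "POLYESTER"
    POLYETHYLENE = "POLYETHYLENE"


class Region(str, enum.Enum):
    """Destination region of a shipment; SSA (sub-Saharan Africa) is the
    reference level in the price model."""

    SSA = "SSA"
    ASIA_PACIFIC = "ASIA_PACIFIC"
    EECA = "EECA"
    LAC = "LAC"
    MENA = "MENA"


@dataclass(frozen=True)
class TransactionRecord:
    """One ITN sale/shipment line.

    Prices are USD per net.  ``unit_price_real`` and ``oil_price_real`` are
    the inflation-adjusted (base-year) values and are ``None`` until a
    deflator table has been applied (or the data are already real).  Oil
    price (USD/barrel) proxies the raw-material (plastics) cost.
    """

    year: int
    supplier: str
    brand: str
    buyer: str
    unit_price_nominal: float
    quantity: int
    net_type: NetType
    fibre_type: FibreType
    area_m2: float
    region: Region
    oil_price_nominal: float | None = None
    unit_price_real: float | None = None
    oil_price_real: float | None = None

    def validate(self, year_range: tuple[int, int] = (2004, 2021)) -> None:
        """Raise ``ValueError`` on any invariant violation."""
        if not self.unit_price_nominal > 0:
            raise ValueError(
                f"unit_price_nominal must be positive, got {self.unit_price_nominal}"
            )
        if self.unit_price_real is not None and not self.unit_price_real > 0:
            raise ValueError(
                f"unit_price_real must be positive, got {self.unit_price_real}"
            )
        if self.quantity < 1:
            raise ValueError(f"quantity must be >= 1, got {self.quantity}")
        if not self.area_m2 > 0:
            raise ValueError(f"area_m2 must be positive, got {self.area_m2}")
        lo, hi = year_range
        if not lo <= self.year <= hi:
            raise ValueError(f"year {self.year} outside configured range {year_range}")


@dataclass(frozen=True)
class DeflatorTable:
    """Year -> multiplier converting nominal USD of that year to base-year USD."""

    base_year: int
    factors: Mapping[int, float]

    def __post_init__(self) -> None:
        if self.base_year not in self.factors:
            raise ValueError(f"base year {self.base_year} missing from factors")
        if not math.isclose(self.factors[self.base_year], 1.0, rel_tol=1e-12):
            raise ValueError("deflator factor for the base year must equal 1")
        for year, f in self.factors.items():
            if not f > 0:
                raise ValueError(f"deflator factor for {year} must be positive, got {f}")

    def factor(self, year: int) -> float:
        try:
            return self.factors[year]
        except KeyError:
            raise KeyError(f"no deflator factor for year {year}") from None


class DistKind(str, enum.Enum):
    POINT = "POINT"
    UNIFORM = "UNIFORM"
    TRIANGULAR = "TRIANGULAR"
    PERT = "PERT"
    NORMAL_TRUNCATED = "NORMAL_TRUNCATED"
    GAMMA = "GAMMA"


#: Required parameter counts per distribution kind.
_N_PARAMS = {
    DistKind.POINT: 1,
    DistKind.UNIFORM: 2,
    DistKind.TRIANGULAR: 3,
    DistKind.PERT: 3,
    DistKind.NORMAL_TRUNCATED: 4,
    DistKind.GAMMA: 2,
}


@dataclass(frozen=True)
class DistributionSpec:
    """A parametric distribution for one uncertain model input.

    Parameter conventions:

    - ``POINT(value)``
    - ``UNIFORM(low, high)``
    - ``TRIANGULAR(low, mode, high)``
    - ``PERT(low, mode, high)`` — beta-PERT with standard shape 4
    - ``NORMAL_TRUNCATED(mu, sigma, low, high)``
    - ``GAMMA(shape, scale)``
    """

    kind: DistKind
    params: tuple[float, ...]

    def __post_init__(self) -> None:
        kind = DistKind(self.kind)
        object.__setattr__(self, "kind", kind)
        object.__setattr__(self, "params", tuple(float(p) for p in self.params))
        n = _N_PARAMS[kind]
        if len(self.params) != n:
            raise ValueError(f"{kind.value} takes {n} parameters, got {len(self.params)}")
        p = self.params
        if kind is DistKind.UNIFORM and not p[0] < p[1]:
            raise ValueError(f"UNIFORM requires low < high, got {p}")
        if kind in (DistKind.TRIANGULAR, DistKind.PERT):
            if not (p[0] <= p[1] <= p[2] and p[0] < p[2]):
                raise ValueError(f"{kind.value} requires low <= mode <= high, low < high, got {p}")
        if kind is DistKind.NORMAL_TRUNCATED:
            if not p[1] > 0:
                raise ValueError(f"NORMAL_TRUNCATED requires sigma > 0, got {p[1]}")
            if not p[2] < p[3]:
                raise ValueError(f"NORMAL_TRUNCATED requires low < high, got {p}")
        if kind is DistKind.GAMMA and not (p[0] > 0 and p[1] > 0):
            raise ValueError(f"GAMMA requires shape, scale > 0, got {p}")

    # -- constructors ----------------------------------------------------
    @classmethod
    def point(cls, value: float) -> "DistributionSpec":
        return cls(DistKind.POINT, (value,))

    @classmethod
    def uniform(cls, low: float, high: float) -> "DistributionSpec":
        return cls(DistKind.UNIFORM, (low, high))

    @classmethod
    def triangular(cls, low: float, mode: float, high: float) -> "DistributionSpec":
        return cls(DistKind.TRIANGULAR, (low, mode, high))

    @classmethod
    def pert(cls, low: float, mode: float, high: float) -> "DistributionSpec":
        return cls(DistKind.PERT, (low, mode, high))

    @classmethod
    def normal_truncated(
        cls, mu: float, sigma: float, low: float = 0.0, high: float = math.inf
    ) -> "DistributionSpec":
        return cls(DistKind.NORMAL_TRUNCATED, (mu, sigma, low, high))

    @classmethod
    def gamma(cls, shape: float, scale: float) -> "DistributionSpec":
        return cls(DistKind.GAMMA, (shape, scale))

    # -- descriptive -----------------------------------------------------
    def support(self) -> tuple[float, float]:
        p = self.params
        if self.kind is DistKind.POINT:
            return (p[0], p[0])
        if self.kind in (DistKind.UNIFORM,):
            return (p[0], p[1])
        if self.kind in (DistKind.TRIANGULAR, DistKind.PERT):
            return (p[0], p[2])
        if self.kind is DistKind.NORMAL_TRUNCATED:
            return (p[2], p[3])
        return (0.0, math.inf)  # GAMMA

    def mean(self) -> float:
        """Analytic mean of the distribution."""
        p = self.params
        if self.kind is DistKind.POINT:
            return p[0]
        if self.kind is DistKind.UNIFORM:
            return 0.5 * (p[0] + p[1])
        if self.kind is DistKind.TRIANGULAR:
            return (p[0] + p[1] + p[2]) / 3.0
        if self.kind is DistKind.PERT:
            return (p[0] + 4.0 * p[1] + p[2]) / 6.0
        if self.kind is DistKind.NORMAL_TRUNCATED:
            from scipy.stats import truncnorm

            mu, sigma, lo, hi = p
            a, b = (lo - mu) / sigma, (hi - mu) / sigma
            return float(truncnorm.mean(a, b, loc=mu, scale=sigma))
        return p[0] * p[1]  # GAMMA shape*scale

    def to_dict(self) -> dict:
        return {"kind": self.kind.value, "params": list(self.params)}

    @classmethod
    def from_dict(cls, d: Mapping) -> "DistributionSpec":
        return cls(DistKind(d["kind"]), tuple(d["params"]))


@dataclass(frozen=True)
class CountryProfile:
    """Per-country inputs for the value-for-money model.

    ``retention_median_b`` is the median time in years a net stays in a
    household before being discarded; ``retention_interval`` is its
    uncertainty interval.  ``price_by_class`` maps a net class (e.g.
    ``"pyrethroid"``, ``"pbo_dual"``) to the baseline price distribution.
    """

    country: str
    retention_median_b: float
    retention_interval: tuple[float, float]
    price_by_class: Mapping[str, DistributionSpec]
    persons_per_net: DistributionSpec
    discount_rate_r: float

    def __post_init__(self) -> None:
        if not self.retention_median_b > 0:
            raise ValueError("retention_median_b must be positive")
        lo, hi = self.retention_interval
        if not lo <= self.retention_median_b <= hi:
            raise ValueError(
                f"retention interval {self.retention_interval} does not bracket "
                f"median {self.retention_median_b}"
            )
        if self.discount_rate_r < 0:
            raise ValueError("discount_rate_r must be >= 0")
        lo_np, hi_np = self.persons_per_net.support()
        if lo_np < 1:
            raise ValueError("persons_per_net support must lie within [1, inf)")

    def retention_spec(self) -> DistributionSpec:
        """Triangular retention distribution over (low, median, high)."""
        lo, hi = self.retention_interval
        if lo == hi:  # degenerate interval: a point estimate
            return DistributionSpec.point(self.retention_median_b)
        return DistributionSpec.triangular(lo, self.retention_median_b, hi)

    def to_dict(self) -> dict:
        return {
            "country": self.country,
            "retention_median_b": self.retention_median_b,
            "retention_interval": list(self.retention_interval),
            "price_by_class": {k: v.to_dict() for k, v in self.price_by_class.items()},
            "persons_per_net": self.persons_per_net.to_dict(),
            "discount_rate_r": self.discount_rate_r,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CountryProfile":
        return cls(
            country=str(d["country"]),
            retention_median_b=float(d["retention_median_b"]),
            retention_interval=tuple(float(x) for x in d["retention_interval"]),
            price_by_class={
                k: DistributionSpec.from_dict(v) for k, v in d["price_by_class"].items()
            },
            persons_per_net=DistributionSpec.from_dict(d["persons_per_net"]),
            discount_rate_r=float(d["discount_rate_r"]),
        )


def replace(record, **changes):
    """Convenience re-export of :func:`dataclasses.replace`."""
    return dataclasses.replace(record, **changes)
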