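"""Supplier-side market concentration: shares, HHI, concentration ratios.

Market share of a supplier in a year is the percentage of all nets shipped
that year that it supplied (quantity-weighted).  The Herfindahl–Hirschman
Index (HHI) is the sum of squared percentage shares, ranging from near 0
(perfect competition) to 10,000 (monopoly); above 1,000 counts as a
concentrated market and above 2,000 as highly concentrated.  The
concentration ratio CR_k is the combined share of the k largest suppliers;
CR5 above 60% indicates an oligopoly.

Transactions whose supplier is unrecorded carry the reserved ``UNKNOWN``
label.  Their treatment is a policy choice, and extreme allocations of the
unknown volume give sensitivity bounds on the HHI.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .records import UNKNOWN_SUPPLIER, TransactionRecord

__all__ = [
    "UnknownPolicy",
    "MarketClass",
    "ShareTable",
    "ConcentrationResult",
    "compute_shares",
    "compute_hhi",
    "compute_cr",
    "hhi_sensitivity_bounds",
    "classify_hhi",
    "concentration_by_year",
    "results_frame",
    "HHI_CONCENTRATED",
    "HHI_HIGHLY_CONCENTRATED",
    "CR_OLIGOPOLY",
]

HHI_CONCENTRATED = 1000.0
HHI_HIGHLY_CONCENTRATED = 2000.0
CR_OLIGOPOLY = 60.0


class UnknownPolicy(str, enum.Enum):
    """How unknown-supplier volume enters an index.

    EXCLUDE_RENORMALIZE drops it and rescales named shares to 100%;
    AS_SINGLE_FIRM treats it as one additional firm; ATOMIZE spreads it over
    vanishingly small independent firms (zero HHI contribution).
    """

    EXCLUDE_RENORMALIZE = "exclude"
    AS_SINGLE_FIRM = "single_firm"
    ATOMIZE = "atomize"


class MarketClass(str, enum.Enum):
    COMPETITIVE = "COMPETITIVE"
    MODERATE = "MODERATE"
    HIGH = "HIGH"


@dataclass(frozen=True)
class ShareTable:
    """Named supplier shares (percent) plus the unknown-supplier share."""

    year: int
    shares: Mapping[str, float]
    unknown_share: float = 0.0

    def __post_init__(self) -> None:
        total = sum(self.shares.values()) + self.unknown_share
        if not math.isclose(total, 100.0, abs_tol=1e-9):
            raise ValueError(f"shares must sum to 100, got {total}")
        if any(s < 0 for s in self.shares.values()) or self.unknown_share < 0:
            raise ValueError("shares must be non-negative")
        if UNKNOWN_SUPPLIER in self.shares:
            raise ValueError("UNKNOWN must be carried in unknown_share, not shares")


@dataclass(frozen=True)
class ConcentrationResult:
    year: int
    hhi: float
    cr_k: float
    k: int
    hhi_bounds: tuple[float, float]
    classification: MarketClass
    unknown_share: float


def compute_shares(
    records: Iterable[TransactionRecord],
    year: int,
    contract_manufacturer_map: Mapping[str, str] | None = None,
) -> ShareTable:
    """Quantity-weighted supplier shares for one year.

    ``contract_manufacturer_map`` re-labels contract manufacturers to their
    parent supplier before aggregation.
    """
    cmap = contract_manufacturer_map or {}
    totals: dict[str, int] = {}
    for r in records:
        if r.year != year:
            continue
        supplier = cmap.get(r.supplier, r.supplier)
        totals[supplier] = totals.get(supplier, 0) + r.quantity
    grand = sum(totals.values())
    if grand == 0:
        raise ValueError(f"no transactions in year {year}")
    unknown = totals.pop(UNKNOWN_SUPPLIER, 0)
    shares = {s: 100.0 * q / grand for s, q in totals.items()}
    return ShareTable(year=year, shares=shares, unknown_share=100.0 * unknown / grand)


def _named(table: ShareTable, policy: UnknownPolicy) -> list[float]:
    """Effective share list after applying the unknown policy."""
    shares = list(table.shares.values())
    if table.unknown_share == 0:
        return shares
    if policy is UnknownPolicy.EXCLUDE_RENORMALIZE:
        named_total = 100.0 - table.unknown_share
        if named_total <= 0:
            raise ValueError("cannot renormalize: all volume has unknown supplier")
        return [100.0 * s / named_total for s in shares]
    if policy is UnknownPolicy.AS_SINGLE_FIRM:
        return shares + [table.unknown_share]
    return shares  # ATOMIZE: unknown contributes nothing


def compute_hhi(
    table: ShareTable, unknown_policy: UnknownPolicy = UnknownPolicy.EXCLUDE_RENORMALIZE
) -> float:
    """Sum of squared percentage shares under the given unknown policy."""
    hhi = sum(s * s for s in _named(table, UnknownPolicy(unknown_policy)))
    return float(min(hhi, 10_000.0))  # renormalization can overshoot by epsilon


def compute_cr(
    table: ShareTable,
    k: int = 5,
    unknown_policy: UnknownPolicy = UnknownPolicy.EXCLUDE_RENORMALIZE,
) -> float:
    """Combined share of the k largest suppliers (percent)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    shares = sorted(_named(table, UnknownPolicy(unknown_policy)), reverse=True)
    return float(min(sum(shares[:k]), 100.0))


def hhi_sensitivity_bounds(table: ShareTable) -> tuple[float, float]:
    """(min, max) HHI over extreme allocations of unknown volume.

    The minimum splits the unknown volume across vanishingly small
    independent firms; the maximum hands it all to the largest named
    supplier.  The bounds coincide exactly when there is no unknown volume.
    """
    shares = list(table.shares.values())
    lo = float(sum(s * s for s in shares))
    if table.unknown_share == 0:
        return (lo, lo)
    if shares:
        top = max(shares)
        hi = lo - top * top + (top + table.unknown_share) ** 2
    else:
        hi = table.unknown_share**2
    return (lo, float(hi))


def classify_hhi(hhi: float) -> MarketClass:
    if hhi > HHI_HIGHLY_CONCENTRATED:
        return MarketClass.HIGH
    if hhi > HHI_CONCENTRATED:
        return MarketClass.MODERATE
    return MarketClass.COMPETITIVE


def concentration_by_year(
    records: Sequence[TransactionRecord],
    k: int = 5,
    unknown_policy: UnknownPolicy = UnknownPolicy.EXCLUDE_RENORMALIZE,
    contract_manufacturer_map: Mapping[str, str] | None = None,
) -> list[ConcentrationResult]:
    """Per-year concentration summary across all years present in the data."""
    years = sorted({r.year for r in records})
    out = []
    for year in years:
        table = compute_shares(records, year, contract_manufacturer_map)
        hhi = compute_hhi(table, unknown_policy)
        out.append(
            ConcentrationResult(
                year=year,
                hhi=hhi,
                cr_k=compute_cr(table, k, unknown_policy),
                k=k,
                hhi_bounds=hhi_sensitivity_bounds(table),
                classification=classify_hhi(hhi),
                unknown_share=table.unknown_share,
            )
        )
    return out


def results_frame(results: Sequence[ConcentrationResult]) -> pd.DataFrame:
    """Long-form table: one row per year."""
    return pd.DataFrame(
        {
            "year": [r.year for r in results],
            "hhi": [r.hhi for r in results],
            "hhi_min": [r.hhi_bounds[0] for r in results],
            "hhi_max": [r.hhi_bounds[1] for r in results],
            f"cr_{results[0].k}" if results else "cr_k": [r.cr_k for r in results],
            "classification": [r.classification.value for r in results],
            "unknown_share": [r.unknown_share for r in results],
        }
    )
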