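"""Tabular readers/writers, deflation and filtering for ITN transactions.

The transaction file format is delimiter-separated text with a header; column
names and the delimiter are configurable because procurement databases do not
share a published schema.  Reading is forgiving at row level: malformed rows
are reported with their line numbers instead of aborting the load.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .records import (
    CountryProfile,
    DeflatorTable,
    FibreType,
    NetType,
    Region,
    TransactionRecord,
)

logger = logging.getLogger("itnvalue")

__all__ = [
    "SchemaConfig",
    "SchemaError",
    "RowError",
    "ReadResult",
    "read_transactions",
    "write_transactions",
    "records_to_frame",
    "records_from_frame",
    "deflate",
    "deflate_transactions",
    "FilterRules",
    "FilterResult",
    "filter_transactions",
    "read_country_profiles",
    "write_country_profiles",
    "read_deflator_table",
]

#: Canonical column order of the transaction CSV.
TRANSACTION_COLUMNS = (
    "year",
    "supplier",
    "brand",
    "buyer",
    "unit_price_nominal",
    "quantity",
    "net_type",
    "fibre_type",
    "area_m2",
    "region",
    "oil_price_nominal",
)

#: Columns present only after deflation; optional on read.
REAL_COLUMNS = ("unit_price_real", "oil_price_real")


class SchemaError(ValueError):
    """A required column is missing or the header cannot be interpreted."""


@dataclass(frozen=True)
class SchemaConfig:
    """Maps canonical field names to file column names.

    ``columns`` overrides individual names; unmapped fields use the canonical
    name itself.  ``year_range`` bounds the accepted calendar years.
    """

    delimiter: str = ","
    columns: dict = field(default_factory=dict)
    year_range: tuple[int, int] = (2004, 2021)

    def column(self, canonical: str) -> str:
        return self.columns.get(canonical, canonical)


@dataclass(frozen=True)
class RowError:
    line: int  # 1-based physical line number in the file (header is line 1)
    message: str


@dataclass(frozen=True)
class ReadResult:
    records: list
    errors: list

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)


def _parse_row(row: dict, schema: SchemaConfig) -> TransactionRecord:
    def get(name: str) -> str:
        return row[schema.column(name)]

    oil = get("oil_price_nominal")
    rec = TransactionRecord(
        year=int(get("year")),
        supplier=str(get("supplier")).strip(),
        brand=str(get("brand")).strip(),
        buyer=str(get("buyer")).strip(),
        unit_price_nominal=float(get("unit_price_nominal")),
        quantity=int(get("quantity")),
        net_type=NetType(str(get("net_type")).strip().upper()),
        fibre_type=FibreType(str(get("fibre_type")).strip().upper()),
        area_m2=float(get("area_m2")),
        region=Region(str(get("region")).strip().upper()),
        oil_price_nominal=None if oil in ("", None) else float(oil),
        unit_price_real=_opt_float(row.get(schema.column("unit_price_real"))),
        oil_price_real=_opt_float(row.get(schema.column("oil_price_real"))),
    )
    rec.validate(year_range=schema.year_range)
    return rec


def _opt_float(v):
    if v is None or v == "" or (isinstance(v, float) and pd.isna(v)):
        return None
    return float(v)


def read_transactions(path, schema: SchemaConfig | None = None) -> ReadResult:
    """Read a transaction table, collecting row-level failures.

    Returns a :class:`ReadResult` whose ``records`` hold every row that
    parsed and validated, and whose ``errors`` carry a
    :class:`RowError` (1-based file line number, message) for each row that
    did not.  A missing required column raises :class:`SchemaError`.
    """
    schema = schema or SchemaConfig()
    df = pd.read_csv(path, sep=schema.delimiter, dtype=str, keep_default_na=False)
    required = [schema.column(c) for c in TRANSACTION_COLUMNS]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    records: list[TransactionRecord] = []
    errors: list[RowError] = []
    for i, row in enumerate(df.to_dict(orient="records")):
        line = i + 2  # header occupies line 1
        try:
            records.append(_parse_row(row, schema))
        except (ValueError, KeyError) as exc:
            errors.append(RowError(line=line, message=str(exc)))
    logger.info(
        "read_transactions: %d records, %d row errors from %s",
        len(records),
        len(errors),
        path,
    )
    return ReadResult(records=records, errors=errors)


def records_to_frame(records: Iterable[TransactionRecord]) -> pd.DataFrame:
    """Transactions as a DataFrame with canonical columns (enums as strings)."""
    rows = []
    for r in records:
        d = dataclasses.asdict(r)
        d["net_type"] = r.net_type.value
        d["fibre_type"] = r.fibre_type.value
        d["region"] = r.region.value
        rows.append(d)
    cols = list(TRANSACTION_COLUMNS) + list(REAL_COLUMNS)
    return pd.DataFrame(rows, columns=cols)


def records_from_frame(df: pd.DataFrame) -> list[TransactionRecord]:
    """Inverse of :func:`records_to_frame`; rows must already be clean."""
    out = []
    for row in df.to_dict(orient="records"):
        out.append(
            TransactionRecord(
                year=int(row["year"]),
                supplier=str(row["supplier"]),
                brand=str(row["brand"]),
                buyer=str(row["buyer"]),
                unit_price_nominal=float(row["unit_price_nominal"]),
                quantity=int(row["quantity"]),
                net_type=NetType(row["net_type"]),
                fibre_type=FibreType(row["fibre_type"]),
                area_m2=float(row["area_m2"]),
                region=Region(row["region"]),
                oil_price_nominal=_opt_float(row.get("oil_price_nominal")),
                unit_price_real=_opt_float(row.get("unit_price_real")),
                oil_price_real=_opt_float(row.get("oil_price_real")),
            )
        )
    return out


def write_transactions(records: Iterable[TransactionRecord], path) -> None:
    """Write transactions as CSV at full stored float precision."""
    df = records_to_frame(records)
    df.to_csv(path, index=False)
    logger.info("write_transactions: %d records to %s", len(df), path)


# ---------------------------------------------------------------------------
# inflation adjustment


def deflate(price_nominal: float, year: int, table: DeflatorTable) -> float:
    """Convert a nominal USD amount of ``year`` to base-year USD."""
    if not price_nominal > 0:
        raise ValueError(f"price must be positive, got {price_nominal}")
    return price_nominal * table.factor(year)


def deflate_transactions(
    records: Iterable[TransactionRecord], table: DeflatorTable
) -> list[TransactionRecord]:
    """Fill ``unit_price_real`` and ``oil_price_real`` from the deflator table."""
    out = []
    for r in records:
        oil_real = (
            None
            if r.oil_price_nominal is None
            else deflate(r.oil_price_nominal, r.year, table)
        )
        out.append(
            dataclasses.replace(
                r,
                unit_price_real=deflate(r.unit_price_nominal, r.year, table),
                oil_price_real=oil_real,
            )
        )
    return out


# ---------------------------------------------------------------------------
# filtering


@dataclass(frozen=True)
class FilterRules:
    """Exclusion rules applied before analysis.

    Untreated nets are not price-comparable with insecticide-treated ones and
    are dropped; ``max_real_price`` is an absolute cap catching data-entry
    outliers (the default 50 USD is far above any plausible per-net price).
    """

    exclude_untreated: bool = True
    max_real_price: float = 50.0


@dataclass(frozen=True)
class FilterResult:
    kept: list
    excluded: list  # list of (record, reason)


REASON_UNTREATED = "untreated"
REASON_PRICE_OUTLIER = "price outlier"


def filter_transactions(
    records: Sequence[TransactionRecord], rules: FilterRules | None = None
) -> FilterResult:
    """Partition records into kept and excluded (with triggering reason).

    The price cap applies to ``unit_price_real`` when available, else to the
    nominal price.  The partition is exact: every input record appears in
    exactly one of the two outputs.
    """
    rules = rules or FilterRules()
    kept, excluded = [], []
    for r in records:
        price = r.unit_price_real if r.unit_price_real is not None else r.unit_price_nominal
        if rules.exclude_untreated and r.net_type is NetType.UNTREATED:
            excluded.append((r, REASON_UNTREATED))
        elif price > rules.max_real_price:
            excluded.append((r, REASON_PRICE_OUTLIER))
        else:
            kept.append(r)
    logger.info(
        "filter_transactions: %d in, %d kept, %d excluded",
        len(records),
        len(kept),
        len(excluded),
    )
    return FilterResult(kept=kept, excluded=excluded)


# ---------------------------------------------------------------------------
# country profiles and deflators (YAML)


def write_country_profiles(profiles: Iterable[CountryProfile], path) -> None:
    data = {"countries": [p.to_dict() for p in profiles]}
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def read_country_profiles(path) -> list[CountryProfile]:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return [CountryProfile.from_dict(d) for d in data["countries"]]


def read_deflator_table(path) -> DeflatorTable:
    """Read a YAML/JSON mapping ``{base_year: int, factors: {year: factor}}``."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return DeflatorTable(
        base_year=int(data["base_year"]),
        factors={int(y): float(f) for y, f in data["factors"].items()},
    )
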