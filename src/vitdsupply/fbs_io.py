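"""Reading FAO food-balance-sheet (FBS) CSV exports.

FAOSTAT publishes FBS data in a long format with one row per
(country, commodity, element, year). The only element this pipeline
consumes is the per-capita food supply quantity, published in
kg/capita/year; every record is converted to g/capita/day on read.

Two FBS generations exist — the "old" sheets (1961–2013) and the "new"
sheets (2014 onward) differ in the balancer methodology FAO used to
produce them. The distinction is carried as metadata only; no attempt is
made to re-balance either series.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import DuplicateKeyError, FormatError, ValidationError

logger = logging.getLogger(__name__)

#: Days per year used for the kg/year -> g/day conversion. FAO per-capita
#: daily quantities are conventionally derived with a 365-day year; leap
#: days are ignored.
DAYS_PER_YEAR: float = 365.0

#: Element label of the rows carrying per-capita food supply mass.
FOOD_SUPPLY_ELEMENT: str = "Food supply quantity (kg/capita/yr)"

#: Columns a FAOSTAT long-format export must provide.
REQUIRED_COLUMNS = ("Area Code", "Area", "Item Code", "Item",
                    "Element", "Year", "Unit", "Value")

#: Canonical tidy columns of a parsed supply table.
CANONICAL_COLUMNS = ("country_code", "country_name", "year",
                     "commodity_code", "commodity_name", "g_per_day")

DIALECTS = ("old_fbs", "new_fbs")


def annual_to_daily(kg_per_year, days_per_year: float = DAYS_PER_YEAR):
    """Convert a per-capita annual supply (kg/year) to daily grams.

    Accepts scalars or numpy/pandas arrays; the map is linear:
    ``g/day = kg/year * 1000 / days_per_year``.

    Raises
    ------
    ValidationError
        If any input value is negative.
    """
    arr = np.asarray(kg_per_year, dtype=float)
    if np.any(arr < 0):
        raise ValidationError("annual supply must be non-negative")
    out = arr * 1000.0 / days_per_year
    return float(out) if np.isscalar(kg_per_year) else out


@dataclass
class SupplyTable:
    """A tidy table of per-capita daily food supply records.

    ``records`` holds one row per (country, year, commodity) with the
    supply in g/capita/day; the key is unique by construction.
    """

    records: pd.DataFrame
    dialect: str
    provenance: str = ""
    unit: str = "g/capita/day"
    dropped_elements: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dialect not in DIALECTS:
            raise ValidationError(
                f"dialect must be one of {DIALECTS}, got {self.dialect!r}")
        missing = set(CANONICAL_COLUMNS) - set(self.records.columns)
        if missing:
            raise FormatError(f"supply table missing columns: {sorted(missing)}")

    @property
    def countries(self) -> list:
        return sorted(self.records["country_code"].unique())

    @property
    def years(self) -> list:
        return sorted(self.records["year"].unique())

    def country_year(self, country_code, year: int) -> pd.DataFrame:
        """Rows for one country/year (possibly empty)."""
        r = self.records
        return r[(r["country_code"] == country_code) & (r["year"] == year)]


def _check_unique(df: pd.DataFrame, keys: Iterable[str], context: str) -> None:
    dup = df.duplicated(subset=list(keys), keep=False)
    if dup.any():
        sample = df.loc[dup, list(keys)].head(5).to_dict("records")
        raise DuplicateKeyError(
            f"duplicate {tuple(keys)} rows in {context}: {sample}")


def read_fbs(path, dialect: str,
             element_label: str = FOOD_SUPPLY_ELEMENT) -> SupplyTable:
    """Parse a FAOSTAT long-format FBS CSV into a :class:`SupplyTable`.

    Only rows whose ``Element`` equals ``element_label`` are kept; all
    other elements (production, imports, kcal/capita/day, ...) are
    counted and logged, never silently discarded. Values are converted
    from kg/capita/year to g/capita/day.

    Raises
    ------
    FormatError
        Missing mandatory column, or non-numeric values (e.g. thousands
        separators — the dialect is UTF-8 with a ``.`` decimal point).
    ValidationError
        Negative supply value (the row index is reported).
    DuplicateKeyError
        Two food-supply rows for the same (country, year, commodity).
    """
    path = Path(path)
    raw = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise FormatError(f"{path.name}: missing mandatory column(s) {missing}")

    kept = raw[raw["Element"] == element_label].copy()
    dropped = (raw.loc[raw["Element"] != element_label, "Element"]
               .value_counts().to_dict())
    if dropped:
        logger.info("read_fbs(%s): dropped %d non-supply rows: %s",
                    path.name, sum(dropped.values()), dropped)

    try:
        values = pd.to_numeric(kept["Value"])
    except (ValueError, TypeError) as exc:
        raise FormatError(
            f"{path.name}: non-numeric Value field ({exc}); "
            "thousands separators are not accepted") from exc
    neg = values.index[values < 0]
    if len(neg):
        raise ValidationError(
            f"{path.name}: negative supply value at row(s) {list(neg[:5])}")

    records = pd.DataFrame({
        "country_code": kept["Area Code"].values,
        "country_name": kept["Area"].astype(str).values,
        "year": pd.to_numeric(kept["Year"]).astype(int).values,
        "commodity_code": kept["Item Code"].values,
        "commodity_name": kept["Item"].astype(str).values,
        "g_per_day": annual_to_daily(values.to_numpy()),
    })
    _check_unique(records, ("country_code", "year", "commodity_code"),
                  path.name)
    return SupplyTable(records=records.reset_index(drop=True),
                       dialect=dialect, provenance=str(path),
                       dropped_elements=dropped)


def write_canonical(table: SupplyTable, path) -> None:
    """Write the tidy canonical CSV (g/capita/day)."""
    table.records.loc[:, list(CANONICAL_COLUMNS)].to_csv(path, index=False)


def to_faostat_csv(table: SupplyTable, path,
                   element_label: str = FOOD_SUPPLY_ELEMENT,
                   days_per_year: float = DAYS_PER_YEAR) -> None:
    """Write a table back out in the FAOSTAT long-format dialect.

    The inverse of :func:`read_fbs` up to floating-point round-trip of
    the g/day ↔ kg/year conversion; used by the synthetic generator and
    for round-trip testing.
    """
    r = table.records
    out = pd.DataFrame({
        "Area Code": r["country_code"],
        "Area": r["country_name"],
        "Item Code": r["commodity_code"],
        "Item": r["commodity_name"],
        "Element Code": 645,
        "Element": element_label,
        "Year": r["year"],
        "Unit": "kg",
        "Value": r["g_per_day"] * days_per_year / 1000.0,
    })
    out.to_csv(path, index=False)
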