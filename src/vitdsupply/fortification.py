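"""Vitamin D fortification of staple vehicles.

Models mandatory or voluntary addition of vitamin D to wheat flour,
maize flour, or fluid milk products, as a per-year increment added on
top of the natural-food supply baseline from a policy's start year
onward. All wheat and maize supply is treated as flour available for
fortification; the fortified fraction is expressed through ``coverage``.
For milk, only part of the FBS milk supply is consumed as the fluid
products covered by fortification policy — that share enters as
``milk_product_share``.

Fortified edible oils are deliberately not modelled: vitamin D retention
under household cooking of oil is too variable to support a defensible
increment, so an ``oil`` policy is refused unless the caller explicitly
configures a retention factor.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Tuple

import pandas as pd
import yaml

from .composition import CommodityMap
from .errors import ConfigurationError, FormatError, ValidationError
from .fbs_io import SupplyTable

logger = logging.getLogger(__name__)

VEHICLES = ("wheat_flour", "maize_flour", "milk", "oil")

#: Default resolution of policy vehicles to composition groups (hence to
#: FBS commodities through the commodity mapping).
DEFAULT_VEHICLE_GROUPS = {
    "wheat_flour": "wheat",
    "maize_flour": "maize",
    "milk": "milk",
    "oil": "vegetable_oils",
}

#: Fluid milk density used to convert g/day of supply to litres.
MILK_DENSITY_G_PER_ML = 1.0


@dataclass(frozen=True)
class FortificationPolicy:
    """One vehicle-level fortification standard for one country.

    ``level`` is μg per kg of flour or μg per litre of milk, depending
    on the vehicle. ``coverage`` is the fraction of the vehicle's supply
    actually fortified (1.0 under well-enforced mandatory standards).
    """

    country_code: object
    vehicle: str
    level: float
    coverage: float = 1.0
    start_year: int = 0
    basis: str = "mandatory"
    milk_product_share: Optional[float] = None

    def __post_init__(self) -> None:
        if self.vehicle not in VEHICLES:
            raise ValidationError(f"unknown vehicle {self.vehicle!r}")
        if self.level < 0:
            raise ValidationError("fortification level must be >= 0")
        if not 0.0 <= self.coverage <= 1.0:
            raise ValidationError("coverage must be within [0, 1]")
        if self.basis not in ("mandatory", "voluntary"):
            raise ValidationError(f"basis must be mandatory/voluntary, "
                                  f"got {self.basis!r}")
        if self.vehicle == "milk":
            if self.milk_product_share is None:
                raise ValidationError(
                    "milk policies require milk_product_share")
            if not 0.0 <= self.milk_product_share <= 1.0:
                raise ValidationError(
                    "milk_product_share must be within [0, 1]")


def flour_increment(vehicle_g_day: float, level_ug_kg: float,
                    coverage: float) -> float:
    """μg/day added by flour fortification.

    ``g/day × coverage × (μg/kg) / 1000``.
    """
    if vehicle_g_day < 0 or level_ug_kg < 0:
        raise ValidationError("flour supply and level must be >= 0")
    if not 0.0 <= coverage <= 1.0:
        raise ValidationError("coverage must be within [0, 1]")
    return vehicle_g_day * coverage * level_ug_kg / 1000.0


def milk_increment(milk_g_day: float, level_ug_L: float, coverage: float,
                   product_share: float,
                   density_g_ml: float = MILK_DENSITY_G_PER_ML) -> float:
    """μg/day added by fluid-milk fortification.

    Supply mass is converted to litres at ``density_g_ml`` (default
    1 g ≈ 1 mL), scaled by the share of milk supply consumed as the
    fortified fluid products and by coverage, then by the μg/L level.
    """
    if milk_g_day < 0 or level_ug_L < 0:
        raise ValidationError("milk supply and level must be >= 0")
    for frac, name in ((coverage, "coverage"), (product_share, "product_share")):
        if not 0.0 <= frac <= 1.0:
            raise ValidationError(f"{name} must be within [0, 1]")
    if density_g_ml <= 0:
        raise ValidationError("density must be > 0")
    litres_day = milk_g_day / (density_g_ml * 1000.0)
    return litres_day * product_share * coverage * level_ug_L


def vehicle_supply(table: SupplyTable, mapping: CommodityMap, country_code,
                   year: int, vehicle: str,
                   vehicle_groups: Mapping[str, str] = DEFAULT_VEHICLE_GROUPS
                   ) -> float:
    """Total g/day of the vehicle's commodities for a country/year."""
    group = vehicle_groups.get(vehicle)
    if group is None:
        raise ConfigurationError(
            f"no composition group configured for vehicle {vehicle!r}")
    rows = table.country_year(country_code, year)
    in_group = rows["commodity_code"].map(
        lambda c: mapping.resolve(c) == group)
    return float(rows.loc[in_group, "g_per_day"].sum())


def policy_increment(policy: FortificationPolicy, vehicle_g_day: float,
                     density_g_ml: float = MILK_DENSITY_G_PER_ML,
                     oil_retention: Optional[float] = None) -> float:
    """μg/day increment of one active policy given its vehicle supply."""
    if policy.vehicle in ("wheat_flour", "maize_flour"):
        return flour_increment(vehicle_g_day, policy.level, policy.coverage)
    if policy.vehicle == "milk":
        return milk_increment(vehicle_g_day, policy.level, policy.coverage,
                              policy.milk_product_share, density_g_ml)
    if policy.vehicle == "oil":
        if oil_retention is None:
            raise ConfigurationError(
                "oil fortification is not modelled unless an explicit "
                "retention factor is configured (cooking losses are too "
                "variable to assume one)")
        return (vehicle_g_day * policy.coverage * policy.level / 1000.0
                * oil_retention)
    raise ConfigurationError(f"unknown vehicle {policy.vehicle!r}")


def apply_policies(baseline: Mapping[int, float],
                   policies: Iterable[FortificationPolicy],
                   table: SupplyTable, mapping: CommodityMap, country_code,
                   vehicle_groups: Mapping[str, str] = DEFAULT_VEHICLE_GROUPS,
                   density_g_ml: float = MILK_DENSITY_G_PER_ML,
                   oil_retention: Optional[float] = None) -> dict:
    """Fortified per-year supply for one country.

    For each year at or after a policy's start year the policy's
    increment is added to the baseline; increments of several policies
    are additive with no interaction. A policy whose country has no
    records in the table is skipped with a warning. Policies apply to
    the whole calendar year of ``start_year``.
    """
    fortified = {int(y): float(v) for y, v in baseline.items()}
    for policy in policies:
        if policy.country_code != country_code:
            continue
        country_rows = table.records[
            table.records["country_code"] == policy.country_code]
        if country_rows.empty:
            logger.warning("policy for %r skipped: country not in table",
                           policy.country_code)
            continue
        for year in fortified:
            if year < policy.start_year:
                continue
            g_day = vehicle_supply(table, mapping, country_code, year,
                                   policy.vehicle, vehicle_groups)
            fortified[year] += policy_increment(
                policy, g_day, density_g_ml, oil_retention)
    return fortified


_POLICY_COLUMNS = ("country_code", "vehicle", "level", "coverage",
                   "start_year", "basis")


def _policy_from_record(rec: Mapping) -> FortificationPolicy:
    share = rec.get("milk_product_share")
    if share is not None and pd.isna(share):
        share = None
    return FortificationPolicy(
        country_code=rec["country_code"], vehicle=str(rec["vehicle"]),
        level=float(rec["level"]), coverage=float(rec.get("coverage", 1.0)),
        start_year=int(rec.get("start_year", 0)),
        basis=str(rec.get("basis", "mandatory")),
        milk_product_share=None if share is None else float(share))


def load_policies(path) -> list:
    """Load policies from CSV (columns as in the schema) or YAML (list
    of mappings under the top-level key ``policies`` or bare)."""
    path = Path(path)
    if path.suffix.lower() in (".yml", ".yaml"):
        doc = yaml.safe_load(path.read_text())
        items = doc.get("policies", doc) if isinstance(doc, dict) else doc
        return [_policy_from_record(rec) for rec in items]
    df = pd.read_csv(path)
    missing = set(_POLICY_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path.name}: missing column(s) {sorted(missing)}")
    return [_policy_from_record(rec) for rec in df.to_dict("records")]
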