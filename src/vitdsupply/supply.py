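"""Per-country vitamin D supply estimation from natural food sources.

The estimate for a country/year is the sum over commodities of
``g/day × content(group)/100`` where content is the group's total
vitamin D in μg/100 g under the chosen 25(OH)D convention. Period
summaries are the arithmetic mean and sample SD across the years of the
period that are present in the data.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .composition import (BioactivityOptions, CommodityMap, CompositionTable,
                          total_content)
from .errors import NotFoundError, ValidationError
from .fbs_io import SupplyTable


@dataclass(frozen=True)
class SupplyEstimate:
    """Mean ± SD per-capita vitamin D supply for one country/period.

    ``sd_ug_day`` is the sample (n−1) standard deviation across the
    years contributing to the period; a single-year period has SD 0.
    """

    country_code: object
    period: Tuple[int, int]
    mean_ug_day: float
    sd_ug_day: float
    n_years: int
    include_ohd: bool = True
    include_fortification: bool = False
    country_name: str = ""

    def __post_init__(self) -> None:
        if self.mean_ug_day < 0 or self.sd_ug_day < 0 or self.n_years < 1:
            raise ValidationError("invalid supply estimate fields")


@dataclass(frozen=True)
class ContributionBreakdown:
    """Share of the period-mean supply contributed by each group."""

    country_code: object
    period: Tuple[int, int]
    shares: Mapping[str, float] = field(default_factory=dict)
    zero_total: bool = False


def _content_lookup(comp: CompositionTable,
                    opts: BioactivityOptions) -> dict:
    return {gid: total_content(entry, opts)
            for gid, entry in comp.entries.items()}


def _ug_day_frame(records: pd.DataFrame, comp: CompositionTable,
                  mapping: CommodityMap, opts: BioactivityOptions) -> pd.DataFrame:
    """Records with resolved group and per-record μg/day contribution."""
    out = records.copy()
    out["group_id"] = out["commodity_code"].map(mapping.resolve)
    content = _content_lookup(comp, opts)
    out["content_per_100g"] = out["group_id"].map(
        lambda g: content.get(g, 0.0) if g is not None else 0.0)
    out["ug_day"] = out["g_per_day"] * out["content_per_100g"] / 100.0
    return out


def country_year_supply(table: SupplyTable, country_code, year: int,
                        comp: CompositionTable, mapping: CommodityMap,
                        opts: BioactivityOptions = BioactivityOptions()) -> float:
    """Vitamin D supply (μg/day) for one country/year.

    Unmapped commodities and groups absent from the composition table
    contribute zero. A country/year with no records at all raises
    :class:`NotFoundError` — an absent observation is not a zero supply.
    """
    rows = table.country_year(country_code, year)
    if rows.empty:
        raise NotFoundError(f"no records for country {country_code!r}, "
                            f"year {year}")
    return float(_ug_day_frame(rows, comp, mapping, opts)["ug_day"].sum())


def yearly_supply(table: SupplyTable, country_code,
                  comp: CompositionTable, mapping: CommodityMap,
                  opts: BioactivityOptions = BioactivityOptions()) -> dict:
    """Map year → μg/day for every year the country appears in."""
    rows = table.records[table.records["country_code"] == country_code]
    if rows.empty:
        raise NotFoundError(f"no records for country {country_code!r}")
    frame = _ug_day_frame(rows, comp, mapping, opts)
    return {int(y): float(v) for y, v in
            frame.groupby("year")["ug_day"].sum().items()}


def period_estimate(yearly: Mapping[int, float], period: Tuple[int, int],
                    country_code=None, *, include_ohd: bool = True,
                    include_fortification: bool = False,
                    country_name: str = "") -> SupplyEstimate:
    """Mean and sample SD over the period's available years.

    Years of the period missing from ``yearly`` are tolerated (the mean
    runs over what is available, with ``n_years`` recording how many);
    zero overlap is an error.
    """
    start, end = period
    values = [yearly[y] for y in range(start, end + 1) if y in yearly]
    if not values:
        raise NotFoundError(
            f"no years of period {start}-{end} present in the data")
    n = len(values)
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if n > 1 else 0.0
    return SupplyEstimate(country_code=country_code, period=(start, end),
                          mean_ug_day=mean, sd_ug_day=sd, n_years=n,
                          include_ohd=include_ohd,
                          include_fortification=include_fortification,
                          country_name=country_name)


def estimate_period(table: SupplyTable, country_code,
                    period: Tuple[int, int], comp: CompositionTable,
                    mapping: CommodityMap,
                    opts: BioactivityOptions = BioactivityOptions()) -> SupplyEstimate:
    """Convenience: yearly supplies then period mean ± SD."""
    yearly = yearly_supply(table, country_code, comp, mapping, opts)
    name = table.records.loc[
        table.records["country_code"] == country_code, "country_name"].iloc[0]
    return period_estimate(yearly, period, country_code,
                           include_ohd=opts.include_ohd, country_name=name)


def contribution_shares(table: SupplyTable, country_code,
                        period: Tuple[int, int], comp: CompositionTable,
                        mapping: CommodityMap,
                        opts: BioactivityOptions = BioactivityOptions()
                        ) -> ContributionBreakdown:
    """Fraction of the period-mean supply coming from each group.

    Shares sum to 1 for a positive total; a zero total yields an empty,
    explicitly flagged breakdown. Unmapped supply never contributes
    (its content is zero), so it carries no share.
    """
    start, end = period
    rows = table.records[
        (table.records["country_code"] == country_code)
        & table.records["year"].between(start, end)]
    if rows.empty:
        raise NotFoundError(f"no records for country {country_code!r} "
                            f"in {start}-{end}")
    frame = _ug_day_frame(rows, comp, mapping, opts)
    frame["group_id"] = frame["group_id"].map(
        lambda g: g if g is not None else "__unmapped__")
    per_group = frame.groupby("group_id")["ug_day"].sum()
    total = float(per_group.sum())
    if total <= 0:
        return ContributionBreakdown(country_code, (start, end),
                                     shares={}, zero_total=True)
    shares = {g: float(v) / total for g, v in per_group.items()}
    return ContributionBreakdown(country_code, (start, end), shares=shares)


def ohd_increment(table: SupplyTable, country_code, period: Tuple[int, int],
                  comp: CompositionTable, mapping: CommodityMap,
                  bioactivity_factor: float = 5.0) -> float:
    """Increment from counting bioactivity-adjusted 25(OH)D3.

    Period mean with the 25(OH)D convention on minus the mean with it
    off; non-negative because content is monotone in the adjustment.
    """
    with_ohd = estimate_period(
        table, country_code, period, comp, mapping,
        BioactivityOptions(True, bioactivity_factor)).mean_ug_day
    without = estimate_period(
        table, country_code, period, comp, mapping,
        BioactivityOptions(include_ohd=False)).mean_ug_day
    return with_ohd - without


def estimate_all(table: SupplyTable, period: Tuple[int, int],
                 comp: CompositionTable, mapping: CommodityMap,
                 opts: BioactivityOptions = BioactivityOptions()) -> pd.DataFrame:
    """Period estimates for every country, as a tidy frame.

    Columns: country_code, country_name, period_start, period_end,
    mean_ug_day, sd_ug_day, n_years, include_ohd, include_fortification.
    """
    rows = []
    names = (table.records.drop_duplicates("country_code")
             .set_index("country_code")["country_name"])
    for country in table.countries:
        try:
            est = estimate_period(table, country, period, comp, mapping, opts)
        except NotFoundError:
            continue
        rows.append({
            "country_code": country,
            "country_name": names.get(country, ""),
            "period_start": period[0], "period_end": period[1],
            "mean_ug_day": est.mean_ug_day, "sd_ug_day": est.sd_ug_day,
            "n_years": est.n_years, "include_ohd": opts.include_ohd,
            "include_fortification": False,
        })
    return pd.DataFrame(rows)
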