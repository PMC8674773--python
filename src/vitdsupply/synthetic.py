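"""Synthetic FBS data with known ground truth.

Generates FAOSTAT-dialect CSV files, composition/mapping tables,
fortification policies and survey pairs for which the true per-capita
vitamin D supply is known by construction, so every pipeline stage can
be tested end-to-end without any download.

The generator models between-year variation as independent truncated
normal multipliers around each commodity group's mean daily supply
(negative draws truncated at zero and counted). Its ground truth is
computed by its own plain-arithmetic loop over the generated records —
deliberately not by the estimation pipeline under test.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .composition import CommodityMap, CompositionEntry, CompositionTable
from .errors import ValidationError
from .fbs_io import DAYS_PER_YEAR, SupplyTable, read_fbs, to_faostat_csv
from .fortification import (DEFAULT_VEHICLE_GROUPS, MILK_DENSITY_G_PER_ML,
                            FortificationPolicy)

#: Default commodity profile: group → (mean g/day, between-year CV).
#: Magnitudes follow typical national diets: plant staples dominate the
#: mass, animal foods carry nearly all the vitamin D.
DEFAULT_PROFILE: dict = {
    "wheat": (250.0, 0.05),
    "rice": (120.0, 0.05),
    "maize": (40.0, 0.08),
    "milk": (300.0, 0.05),
    "eggs": (25.0, 0.08),
    "bovine_meat": (40.0, 0.08),
    "pelagic_fish": (30.0, 0.15),
    "demersal_fish": (15.0, 0.15),
    "vegetable_oils": (35.0, 0.05),
}

DEFAULT_COMPOSITION = (
    CompositionEntry("wheat", "Wheat and products", 0.0, 0.0, "illustrative"),
    CompositionEntry("rice", "Rice and products", 0.0, 0.0, "illustrative"),
    CompositionEntry("maize", "Maize and products", 0.0, 0.0, "illustrative"),
    CompositionEntry("milk", "Milk, excluding butter", 0.05, 0.01, "illustrative"),
    CompositionEntry("eggs", "Eggs", 2.9, 0.45, "illustrative"),
    CompositionEntry("bovine_meat", "Bovine meat", 0.5, 0.15, "illustrative"),
    CompositionEntry("pelagic_fish", "Pelagic fish", 8.0, 0.2, "illustrative"),
    CompositionEntry("demersal_fish", "Demersal fish", 2.5, 0.05, "illustrative"),
    CompositionEntry("vegetable_oils", "Vegetable oils", 0.0, 0.0, "illustrative"),
)


@dataclass
class SyntheticConfig:
    """Knobs of the generator; deterministic given ``seed``."""

    n_countries: int = 5
    years: Tuple[int, int] = (2014, 2017)
    commodity_profile: Mapping[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PROFILE))
    composition: Sequence[CompositionEntry] = DEFAULT_COMPOSITION
    policies: Sequence[FortificationPolicy] = ()
    bioactivity_factor: float = 5.0
    seed: int = 0
    # survey-pair generation
    n_pairs: int = 10
    survey_bias: float = 0.5
    survey_noise: float = 0.5

    def __post_init__(self) -> None:
        if self.n_countries < 1 or self.years[0] > self.years[1]:
            raise ValidationError("need >= 1 country and a valid year range")
        if self.n_pairs < 3:
            raise ValidationError("need >= 3 survey pairs")
        for g, (mean, cv) in self.commodity_profile.items():
            if mean < 0 or cv < 0:
                raise ValidationError(f"negative mean/CV for group {g!r}")


@dataclass
class SyntheticDataset:
    """Everything a pipeline run needs, plus the independent ground truth.

    ``ground_truth`` has one row per country/year with the true supply
    under the four option combinations (with/without 25(OH)D, with/
    without fortification), in μg/day.
    """

    table: SupplyTable
    composition: CompositionTable
    mapping: CommodityMap
    policies: Sequence[FortificationPolicy]
    ground_truth: pd.DataFrame
    fbs_csv: Path
    n_truncated: int


def _country_codes(n: int) -> list:
    return [f"SYN{i + 1:03d}" for i in range(n)]


def generate_fbs(config: SyntheticConfig, out_dir) -> SyntheticDataset:
    """Generate an FBS CSV plus ground truth into ``out_dir``.

    The CSV is written in the FAOSTAT long-format dialect and parsed
    back through :func:`vitdsupply.fbs_io.read_fbs`, so the returned
    table is exactly what a pipeline consumer would see.
    """
    rng = np.random.default_rng(config.seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    groups = list(config.commodity_profile)
    comp = {e.group_id: e for e in config.composition}
    missing = [g for g in groups if g not in comp]
    if missing:
        raise ValidationError(f"profile groups without composition: {missing}")
    codes = {g: 2500 + i for i, g in enumerate(groups)}

    years = list(range(config.years[0], config.years[1] + 1))
    countries = _country_codes(config.n_countries)
    # per-country scale so countries differ systematically, not only by noise
    country_scale = {c: 0.6 + 0.2 * i for i, c in enumerate(countries)}

    rows, n_trunc = [], 0
    supplies: dict = {}  # (country, year, group) -> g/day
    for country in countries:
        for year in years:
            for group in groups:
                mean, cv = config.commodity_profile[group]
                level = mean * country_scale[country]
                draw = level * (1.0 + cv * rng.standard_normal()) if cv > 0 else level
                if draw < 0:
                    draw, n_trunc = 0.0, n_trunc + 1
                supplies[(country, year, group)] = draw
                rows.append({
                    "Area Code": country, "Area": f"Synthland {country[-3:]}",
                    "Item Code": codes[group],
                    "Item": comp[group].group_name,
                    "Element Code": 645,
                    "Element": "Food supply quantity (kg/capita/yr)",
                    "Year": year, "Unit": "kg",
                    "Value": draw * DAYS_PER_YEAR / 1000.0,
                })

    fbs_csv = out_dir / "synthetic_fbs.csv"
    pd.DataFrame(rows).to_csv(fbs_csv, index=False)

    # ---- independent ground truth: plain loops, no pipeline calls ----
    factor = config.bioactivity_factor
    truth_rows = []
    for country in countries:
        for year in years:
            total = excl = 0.0
            for group in groups:
                g_day = supplies[(country, year, group)]
                e = comp[group]
                excl += g_day * e.vitd3_per_100g / 100.0
                total += g_day * (e.vitd3_per_100g
                                  + factor * e.ohd3_per_100g) / 100.0
            inc = 0.0
            for pol in config.policies:
                if pol.country_code != country or year < pol.start_year:
                    continue
                vg = DEFAULT_VEHICLE_GROUPS[pol.vehicle]
                g_day = supplies.get((country, year, vg), 0.0)
                if pol.vehicle == "milk":
                    inc += (g_day / (MILK_DENSITY_G_PER_ML * 1000.0)
                            * pol.milk_product_share * pol.coverage * pol.level)
                else:
                    inc += g_day * pol.coverage * pol.level / 1000.0
            truth_rows.append({
                "country_code": country, "year": year,
                "natural_excl_ohd": excl, "natural_total": total,
                "fortified_excl_ohd": excl + inc,
                "fortified_total": total + inc,
            })
    ground_truth = pd.DataFrame(truth_rows)
    ground_truth.to_csv(out_dir / "ground_truth.csv", index=False)

    mapping = CommodityMap({codes[g]: g for g in groups})
    table = read_fbs(fbs_csv, dialect="new_fbs" if years[0] >= 2014 else "old_fbs")
    return SyntheticDataset(
        table=table, composition=CompositionTable.from_entries(config.composition),
        mapping=mapping, policies=tuple(config.policies),
        ground_truth=ground_truth, fbs_csv=fbs_csv, n_truncated=n_trunc)


def generate_survey_pairs(config: SyntheticConfig,
                          out_path=None) -> Tuple[pd.DataFrame, float]:
    """Paired survey-intake / FBS-supply data with a planted bias.

    The FBS column equals the survey column plus ``survey_bias`` plus
    Gaussian noise of SD ``survey_noise`` (truncated at zero). Returns
    the pair frame and the true planted bias.
    """
    rng = np.random.default_rng(config.seed + 1)
    countries = [f"SRV{i + 1:03d}" for i in range(config.n_pairs)]
    survey = rng.uniform(1.0, 6.0, size=config.n_pairs)
    fbs = survey + config.survey_bias + config.survey_noise * rng.standard_normal(config.n_pairs)
    fbs = np.clip(fbs, 0.0, None)
    df = pd.DataFrame({
        "country_code": countries,
        "survey_years": "2014-2017",
        "survey_intake_ug_day": survey,
        "fbs_supply_ug_day": fbs,
        "ohd_convention": "excluded",
    })
    if out_path is not None:
        df.to_csv(out_path, index=False)
    return df, config.survey_bias
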