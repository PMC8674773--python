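"""Packaged reference data.

Two kinds of data ship with the package:

* Published per-country vitamin D supply estimates (mean ± SD, μg/day)
  for the 2004–2013 and 2014–2017 FBS periods, under both 25(OH)D
  conventions, and the corresponding fortified estimates for the eight
  countries where fortification of flour or milk is common. These are
  the reference values the acceptance checks reproduce summaries from.
* An illustrative composition table and commodity mapping for examples
  and tests (not a transcription of any national database), and a UN
  continental-region assignment for the reference countries.
"""
from __future__ import annotations

from importlib import resources

import pandas as pd

from .composition import CommodityMap, CompositionTable

PERIODS = ("2004-2013", "2014-2017")


def _data_path(name: str):
    return resources.files("vitdsupply.data") / name


def load_reference_natural() -> pd.DataFrame:
    """Natural-food supply estimates: country, period, total_mean,
    total_sd, excl_ohd_mean, excl_ohd_sd (μg/day, 1-decimal)."""
    return pd.read_csv(_data_path("natural_supply_reference.csv"))


def load_reference_fortified() -> pd.DataFrame:
    """Fortified vs natural supply estimates (2014–2017) for the eight
    countries with common flour or milk fortification."""
    return pd.read_csv(_data_path("fortified_supply_reference.csv"))


def load_region_map() -> dict:
    """country → continental region (Africa/Americas/Asia/Europe/Oceania)."""
    df = pd.read_csv(_data_path("un_regions.csv"))
    return dict(zip(df["country"], df["region"]))


def load_example_composition() -> CompositionTable:
    """The illustrative composition table (see module docstring)."""
    return CompositionTable.from_csv(_data_path("composition_illustrative.csv"))


def load_example_mapping() -> CommodityMap:
    """The illustrative FAOSTAT commodity-code → group mapping."""
    return CommodityMap.from_csv(_data_path("commodity_mapping_illustrative.csv"))


def reference_means(period: str, convention: str = "excl_ohd") -> pd.Series:
    """Per-country mean supply for one period as a Series.

    ``convention`` is ``"excl_ohd"`` (vitamin D3 only) or ``"total"``
    (including bioactivity-adjusted 25(OH)D3).
    """
    if period not in PERIODS:
        raise ValueError(f"period must be one of {PERIODS}")
    col = {"excl_ohd": "excl_ohd_mean", "total": "total_mean"}[convention]
    df = load_reference_natural()
    sub = df[df["period"] == period]
    return pd.Series(sub[col].values, index=sub["country"].values, name=col)
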