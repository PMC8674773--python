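"""Banding, extremes, regional summaries and between-period deltas.

Supply estimates are reported at one decimal place (μg/day), and the
six classification bands tile that one-decimal grid with no gaps:
≤1.5, 1.6–3.0, 3.1–5.5, 5.6–7.5, 7.6–10.0, >10.0. Classification
rounds half-up to one decimal first, so e.g. 1.54 falls in the lowest
band and 1.55 in the second.
"""
from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import DuplicateKeyError, ValidationError

REGIONS = ("Africa", "Americas", "Asia", "Europe", "Oceania")


def round1(x: float) -> float:
    """Round half-up to one decimal (presentation/banding rounding).

    Python's built-in ``round`` is banker's rounding; reported values
    use conventional half-up instead (0.25 → 0.3).
    """
    return float(Decimal(repr(float(x))).quantize(Decimal("0.1"),
                                                  rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class Band:
    """One closed band on the one-decimal grid; ``hi=None`` is open-ended."""

    label: str
    lo: float
    hi: Optional[float]

    def contains(self, rounded: float) -> bool:
        if rounded < self.lo:
            return False
        return self.hi is None or rounded <= self.hi


@dataclass(frozen=True)
class BandScheme:
    """An ordered, gap-free partition of the non-negative 1-decimal grid."""

    bands: Tuple[Band, ...]

    def labels(self) -> list:
        return [b.label for b in self.bands]


DEFAULT_BANDS = BandScheme(bands=(
    Band("<=1.5", 0.0, 1.5),
    Band("1.6-3.0", 1.6, 3.0),
    Band("3.1-5.5", 3.1, 5.5),
    Band("5.6-7.5", 5.6, 7.5),
    Band("7.6-10.0", 7.6, 10.0),
    Band(">10.0", 10.1, None),
))


def classify_band(mean_ug_day: float,
                  scheme: BandScheme = DEFAULT_BANDS) -> str:
    """Band label for a supply mean (rounded half-up to 1 decimal first)."""
    if mean_ug_day < 0:
        raise ValidationError("supply mean must be non-negative")
    r = round1(mean_ug_day)
    for band in scheme.bands:
        if band.contains(r):
            return band.label
    raise ValidationError(f"value {r} not covered by the band scheme")


def band_counts(means: Mapping, scheme: BandScheme = DEFAULT_BANDS
                ) -> "OrderedDict[str, int]":
    """Countries per band; ``means`` maps country → mean μg/day.

    Accepts a dict or a pandas Series indexed by country (one entry per
    country; duplicates error). Counts always sum to the number of
    countries because the bands partition the rounded grid.
    """
    series = pd.Series(means, dtype=float)
    if series.index.duplicated().any():
        dups = series.index[series.index.duplicated()].tolist()
        raise DuplicateKeyError(f"duplicate countries in band input: {dups}")
    counts = OrderedDict((label, 0) for label in scheme.labels())
    for value in series:
        counts[classify_band(value, scheme)] += 1
    return counts


def extremes(means: Mapping) -> Tuple[Tuple[float, list], Tuple[float, list]]:
    """((min value, argmin countries), (max value, argmax countries)).

    Ties are returned as lists of all countries attaining the extreme.
    """
    series = pd.Series(means, dtype=float)
    if series.empty:
        raise ValidationError("extremes of an empty table are undefined")
    lo, hi = series.min(), series.max()
    return ((float(lo), sorted(series.index[series == lo].tolist())),
            (float(hi), sorted(series.index[series == hi].tolist())))


@dataclass(frozen=True)
class RegionSummary:
    region: str
    median: float
    q25: float
    q75: float
    n_countries: int

    def __post_init__(self) -> None:
        if not self.q25 <= self.median <= self.q75:
            raise ValidationError("quartiles out of order")


def region_summary(means: Mapping, region_map: Mapping,
                   interpolation: str = "linear") -> list:
    """Median and quartiles of country means within each region.

    ``region_map`` maps country → region name; countries without an
    assignment are excluded (and reported via the return's coverage —
    they simply do not appear). Quantiles use numpy with the given
    interpolation (``linear`` = the common type-7 default).
    """
    series = pd.Series(means, dtype=float)
    rows = []
    for region in REGIONS:
        members = [c for c in series.index if region_map.get(c) == region]
        if not members:
            continue
        vals = series[members].to_numpy()
        q25, med, q75 = np.quantile(vals, [0.25, 0.5, 0.75],
                                    method=interpolation)
        rows.append(RegionSummary(region=region, median=float(med),
                                  q25=float(q25), q75=float(q75),
                                  n_countries=len(members)))
    return rows


DELTA_CLASSES = ("<0.5", "0.5-0.99", ">=1.0")


def classify_delta(delta: float) -> str:
    """Magnitude class of a between-period change in mean supply."""
    a = abs(delta)
    if a < 0.5:
        return "<0.5"
    if a < 1.0:
        return "0.5-0.99"
    return ">=1.0"


def period_delta(means_a: Mapping, means_b: Mapping) -> pd.DataFrame:
    """Per-country change from period A to period B.

    Returns a frame indexed by the countries present in both periods
    with columns ``delta`` (B − A) and ``delta_class``; countries seen
    in only one period are listed in the frame's ``attrs['only_a']`` /
    ``attrs['only_b']``.
    """
    a = pd.Series(means_a, dtype=float)
    b = pd.Series(means_b, dtype=float)
    common = a.index.intersection(b.index)
    delta = (b[common] - a[common]).rename("delta")
    out = delta.to_frame()
    out["delta_class"] = out["delta"].map(classify_delta)
    out.attrs["only_a"] = sorted(a.index.difference(b.index).tolist())
    out.attrs["only_b"] = sorted(b.index.difference(a.index).tolist())
    return out
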