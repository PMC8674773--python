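"""Bland-Altman agreement between supply estimates and survey intakes.

Food-balance-sheet supply is an availability measure and is expected to
sit slightly above survey-measured intake (waste and distribution are
not modelled), so the interesting quantities are the mean difference
(bias), its SD, the 95% limits of agreement (bias ± 1.96 SD), and a
proportional-bias check — an ordinary least-squares regression of the
per-country differences on the per-country pair means, whose slope
p-value tests whether disagreement grows with the measured level.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import ValidationError


@dataclass(frozen=True)
class PairedEstimate:
    """One country's survey intake and matched FBS supply, μg/day.

    The FBS comparator must use the same years and the same 25(OH)D
    convention as the survey it is paired with.
    """

    country_code: object
    survey_intake: float
    fbs_supply: float
    survey_years: str = ""

    def __post_init__(self) -> None:
        if self.survey_intake < 0 or self.fbs_supply < 0:
            raise ValidationError("intake and supply must be non-negative")


@dataclass(frozen=True)
class ConcordanceResult:
    """Bland-Altman statistics for a set of paired estimates."""

    n: int
    bias: float
    bias_sd: float
    loa_low: float
    loa_high: float
    bias_range: Tuple[float, float]
    proportional_bias_p: float

    def __post_init__(self) -> None:
        if not self.loa_low - 1e-12 <= self.bias <= self.loa_high + 1e-12:
            raise ValidationError("limits of agreement must bracket the bias")


def bland_altman(pairs: Iterable[PairedEstimate]) -> ConcordanceResult:
    """Bland-Altman analysis of FBS supply vs survey intake.

    Differences are taken as ``fbs − survey`` so a positive bias means
    the supply proxy overestimates intake. Requires n ≥ 3 (the SD and
    the regression slope are degenerate below that). When the
    differences have zero variance the proportional-bias p is NaN.
    """
    pairs = list(pairs)
    n = len(pairs)
    if n < 3:
        raise ValidationError(f"Bland-Altman needs >= 3 pairs, got {n}")
    fbs = np.array([p.fbs_supply for p in pairs], dtype=float)
    survey = np.array([p.survey_intake for p in pairs], dtype=float)
    diff = fbs - survey
    mean_pair = (fbs + survey) / 2.0
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    if sd > 0 and np.ptp(mean_pair) > 0:
        model = sm.OLS(diff, sm.add_constant(mean_pair)).fit()
        p_slope = float(model.pvalues[1])
    else:
        p_slope = float("nan")
    return ConcordanceResult(
        n=n, bias=bias, bias_sd=sd,
        loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd,
        bias_range=(float(diff.min()), float(diff.max())),
        proportional_bias_p=p_slope)


def pairs_from_frame(df: pd.DataFrame) -> list:
    """Build pairs from a CSV-shaped frame.

    Expected columns: country_code, survey_intake_ug_day,
    fbs_supply_ug_day, and optionally survey_years.
    """
    return [PairedEstimate(
        country_code=r["country_code"],
        survey_intake=float(r["survey_intake_ug_day"]),
        fbs_supply=float(r["fbs_supply_ug_day"]),
        survey_years=str(r.get("survey_years", "")))
        for r in df.to_dict("records")]


def result_frame(result: ConcordanceResult) -> pd.DataFrame:
    """Single-row tidy frame of the agreement statistics."""
    return pd.DataFrame([{
        "n": result.n, "bias": result.bias, "bias_sd": result.bias_sd,
        "loa_low": result.loa_low, "loa_high": result.loa_high,
        "bias_min": result.bias_range[0], "bias_max": result.bias_range[1],
        "proportional_bias_p": result.proportional_bias_p,
    }])


def plot_bland_altman(pairs: Sequence[PairedEstimate],
                      result: Optional[ConcordanceResult] = None,
                      path=None):
    """Standard Bland-Altman scatter (differences vs pair means).

    Returns the matplotlib figure; writes it to ``path`` if given.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if result is None:
        result = bland_altman(pairs)
    fbs = np.array([p.fbs_supply for p in pairs], dtype=float)
    survey = np.array([p.survey_intake for p in pairs], dtype=float)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter((fbs + survey) / 2, fbs - survey, color="tab:blue")
    ax.axhline(result.bias, color="k", label=f"bias {result.bias:.2f}")
    for y in (result.loa_low, result.loa_high):
        ax.axhline(y, color="k", linestyle="--")
    ax.set_xlabel("mean of FBS supply and survey intake (µg/d)")
    ax.set_ylabel("FBS supply − survey intake (µg/d)")
    ax.legend(frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
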