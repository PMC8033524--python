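"""In-vivo quantitative procedures: calliper tumour volume, log-linear
time-to-threshold growth fits, 2^-ddCt relative expression, and
ChIP-qPCR percent-input.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats


def tumour_volume(large_diam: float, small_diam: float) -> float:
    """Ellipsoid-approximation tumour volume from two calliper diameters.

    V = 0.5 x large x small^2 (mm^3).  If the diameters are given in the
    wrong order they are swapped with a warning.
    """
    if small_diam <= 0 or large_diam <= 0:
        raise ValueError("diameters must be positive")
    if small_diam > large_diam:
        warnings.warn("small_diam > large_diam; swapping")
        large_diam, small_diam = small_diam, large_diam
    return 0.5 * large_diam * small_diam ** 2


@dataclass
class GrowthSeries:
    """Calliper-derived volume measurements for one animal."""

    animal_id: str
    t: Sequence[float]  # days, strictly increasing
    V: Sequence[float]  # mm^3, >= 0
    condition: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        if len(t) != len(self.V):
            raise ValueError("t and V must have equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("t must be strictly increasing")
        if np.any(np.asarray(self.V, dtype=float) < 0):
            raise ValueError("volumes must be >= 0")


@dataclass(frozen=True)
class GrowthFit:
    """OLS fit of log(volume) on time and the derived time to threshold."""

    animal_id: str
    intercept: float  # log-volume units (natural log)
    slope: float  # per day
    r_squared: float
    t_threshold: Optional[float]  # days; None when growth rate <= 0
    threshold: float
    extrapolated: bool
    n_points: int


class UndefinedFitError(ValueError):
    """Fewer than two positive volumes: the log-linear fit is undefined."""


def time_to_threshold(series: GrowthSeries, V_star: float = 250.0) -> GrowthFit:
    """Estimate the time to reach a volume threshold from a log-linear fit.

    Ordinary least squares of ln(V) on t over the V > 0 points;
    ``t_threshold = (ln V* - intercept) / slope``.  The natural log is used
    internally; the estimated time is invariant to the log base.  When the
    fitted slope is not positive the threshold is never reached and
    ``t_threshold`` is None.  The estimate is flagged as extrapolated when
    it falls outside the observed time range.
    """
    t = np.asarray(series.t, dtype=float)
    v = np.asarray(series.V, dtype=float)
    mask = v > 0
    if mask.sum() < 2:
        raise UndefinedFitError(
            f"{series.animal_id}: need >= 2 positive volumes, got {int(mask.sum())}")
    t_fit, v_fit = t[mask], np.log(v[mask])
    res = stats.linregress(t_fit, v_fit)
    slope, intercept = float(res.slope), float(res.intercept)
    r2 = float(res.rvalue ** 2) if not math.isnan(res.rvalue) else 1.0
    if slope > 0:
        t_star = (math.log(V_star) - intercept) / slope
        extrap = not (t_fit.min() <= t_star <= t_fit.max())
    else:
        t_star, extrap = None, False
    return GrowthFit(animal_id=series.animal_id, intercept=intercept,
                     slope=slope, r_squared=r2, t_threshold=t_star,
                     threshold=V_star, extrapolated=extrap,
                     n_points=int(mask.sum()))


def read_growth_table(path) -> list[GrowthSeries]:
    """Read a calliper table (animal_id, day, large_mm, small_mm[, condition])
    into per-animal volume series via :func:`tumour_volume`."""
    df = pd.read_csv(path, sep="\t")
    required = {"animal_id", "day", "large_mm", "small_mm"}
    if not required <= set(df.columns):
        raise ValueError(f"growth table needs columns {sorted(required)}")
    out = []
    for animal, sub in df.groupby("animal_id", sort=True):
        sub = sub.sort_values("day")
        vols = [tumour_volume(l, s) for l, s in zip(sub["large_mm"], sub["small_mm"])]
        cond = str(sub["condition"].iloc[0]) if "condition" in sub else ""
        out.append(GrowthSeries(str(animal), sub["day"].tolist(), vols, cond))
    return out


# ---------------------------------------------------------------------------
# qPCR / ChIP-qPCR quantification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QpcrMeasurement:
    """Mean Ct of a target and its housekeeping gene in one condition.

    Technical-replicate Cts should be averaged arithmetically before
    constructing the measurement (see :func:`mean_ct`).
    """

    ct_target: float
    ct_housekeeping: float

    def __post_init__(self) -> None:
        for v in (self.ct_target, self.ct_housekeeping):
            if not (v > 0 and math.isfinite(v)):
                raise ValueError("Ct values must be positive and finite")

    @property
    def delta_ct(self) -> float:
        return self.ct_target - self.ct_housekeeping


def mean_ct(replicate_cts: Sequence[float]) -> float:
    """Arithmetic mean of technical-replicate Ct values."""
    if not len(replicate_cts):
        raise ValueError("no Ct values")
    return float(np.mean(replicate_cts))


def ddct_fold_change(sample: QpcrMeasurement, control: QpcrMeasurement) -> float:
    """Relative expression by the 2^-ddCt method.

    dCt = Ct_target - Ct_housekeeping per condition; the fold change versus
    the control condition is 2^-(dCt_sample - dCt_control).
    """
    ddct = sample.delta_ct - control.delta_ct
    return 2.0 ** (-ddct)


def percent_input(ct_ip: float, ct_input: float, input_fraction: float) -> float:
    """ChIP-qPCR percent-input quantification.

    The input Ct is adjusted for the dilution of the input aliquot
    (``adjusted = Ct_input - log2(1 / input_fraction)``) and the IP signal
    expressed as ``100 * 2^(adjusted - Ct_IP)``.
    """
    if not 0 < input_fraction <= 1:
        raise ValueError("input_fraction must be in (0, 1]")
    adjusted = ct_input - math.log2(1.0 / input_fraction)
    return 100.0 * 2.0 ** (adjusted - ct_ip)


# ---------------------------------------------------------------------------
# Downstream comparisons (utility, standard formulas)
# ---------------------------------------------------------------------------

def t_test(x: Sequence[float], y: Sequence[float], welch: bool = False,
           ) -> tuple[float, float]:
    """Two-sided Student's (or Welch's) t-test on two samples."""
    res = stats.ttest_ind(np.asarray(x, float), np.asarray(y, float),
                          equal_var=not welch)
    return float(res.statistic), float(res.pvalue)
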