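"""Non-compartmental PK summaries and small statistical helpers.

Provides trapezoidal AUC, Cmax/Tmax with local quadratic refinement,
log-linear terminal-slope regression, and the comparison statistics used
when screening compounds: geometric mean with a 2.5-97.5% interval, the
inclusive two-fold significance rule, and Pearson correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .pbpk import PKProfile

__all__ = [
    "PKMetrics",
    "ObservedSeries",
    "MetricsError",
    "compute_pk_metrics",
    "terminal_slope",
    "geometric_mean_ci",
    "fold_change_flag",
    "FoldChange",
    "pearson_r",
]

LN2 = math.log(2.0)


class MetricsError(ValueError):
    """Raised on degenerate inputs to a metric computation."""


@dataclass(frozen=True)
class ObservedSeries:
    """A user-supplied observed concentration-time table."""

    time_h: np.ndarray
    concentration_ng_mL: np.ndarray
    label: str = "observed"

    def __post_init__(self) -> None:
        t = np.asarray(self.time_h, dtype=float)
        c = np.asarray(self.concentration_ng_mL, dtype=float)
        if t.shape != c.shape:
            raise MetricsError("time and concentration must have equal length")
        if np.any(t < 0) or np.any(np.diff(t) < 0):
            raise MetricsError("times must be non-negative and sorted")
        object.__setattr__(self, "time_h", t)
        object.__setattr__(self, "concentration_ng_mL", c)


@dataclass(frozen=True)
class PKMetrics:
    auc_0_t: float  # ng*h/mL
    auc_0_inf: float  # ng*h/mL; NaN when the terminal slope is undefined
    cmax: float  # ng/mL
    tmax: float  # h
    terminal_half_life: float  # h
    lambda_z: float  # 1/h
    lambda_z_r_squared: float = math.nan

    def to_dict(self) -> dict:
        return {
            "auc_0_t_ng_h_mL": self.auc_0_t,
            "auc_0_inf_ng_h_mL": self.auc_0_inf,
            "cmax_ng_mL": self.cmax,
            "tmax_h": self.tmax,
            "terminal_half_life_h": self.terminal_half_life,
            "lambda_z_1_h": self.lambda_z,
        }


def terminal_slope(
    time_h: Sequence[float],
    concentration: Sequence[float],
    window: tuple[float, float] | None = None,
) -> tuple[float, float]:
    """Terminal elimination rate by log-linear least squares.

    Returns ``(lambda_z, r_squared)`` where ``lambda_z`` is the negative
    of the regression slope of ln(C) on t over the window.  The default
    window is the last 30% of the sampled span.  Requires at least three
    strictly positive concentrations in the window.
    """
    t = np.asarray(time_h, dtype=float)
    c = np.asarray(concentration, dtype=float)
    if window is None:
        window = (t[0] + 0.7 * (t[-1] - t[0]), t[-1])
    lo, hi = window
    mask = (t >= lo) & (t <= hi) & (c > 0)
    if mask.sum() < 3:
        raise MetricsError(
            f"terminal regression needs >=3 positive points in [{lo}, {hi}], "
            f"found {int(mask.sum())}"
        )
    x = t[mask]
    y = np.log(c[mask])
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 if ss_tot == 0 else 1.0 - np.sum(resid**2) / ss_tot
    return -slope, float(r2)


def _refine_peak(t: np.ndarray, c: np.ndarray) -> tuple[float, float]:
    """Quadratic refinement of (cmax, tmax) through the grid maximum."""
    i = int(np.argmax(c))
    if i == 0 or i == len(c) - 1:
        return float(c[i]), float(t[i])
    t0, t1, t2 = t[i - 1], t[i], t[i + 1]
    y0, y1, y2 = c[i - 1], c[i], c[i + 1]
    denom = (t0 - t1) * (t0 - t2) * (t1 - t2)
    a = (t2 * (y1 - y0) + t1 * (y0 - y2) + t0 * (y2 - y1)) / denom
    b = (t2**2 * (y0 - y1) + t1**2 * (y2 - y0) + t0**2 * (y1 - y2)) / denom
    if a >= 0:  # flat or degenerate; keep the grid point
        return float(y1), float(t1)
    tv = -b / (2 * a)
    if not t0 <= tv <= t2:
        return float(y1), float(t1)
    cc = (
        y0 * (tv - t1) * (tv - t2) / ((t0 - t1) * (t0 - t2))
        + y1 * (tv - t0) * (tv - t2) / ((t1 - t0) * (t1 - t2))
        + y2 * (tv - t0) * (tv - t1) / ((t2 - t0) * (t2 - t1))
    )
    return float(cc), float(tv)


def compute_pk_metrics(
    profile: PKProfile,
    t_end: float | None = None,
    terminal_window: tuple[float, float] | None = None,
) -> PKMetrics:
    """NCA summary of a simulated plasma profile over [0, t_end]."""
    t = profile.time_h
    c = profile.plasma_ng_mL
    if t_end is not None:
        if t_end > t[-1]:
            raise MetricsError(f"profile ends at {t[-1]} h, before t_end={t_end}")
        mask = t <= t_end + 1e-12
        t, c = t[mask], c[mask]
    auc_0_t = float(np.trapezoid(c, t))
    cmax, tmax = _refine_peak(t, c)
    if np.all(c == 0):
        return PKMetrics(0.0, math.nan, 0.0, 0.0, math.nan, math.nan)
    try:
        lam, r2 = terminal_slope(t, c, terminal_window)
    except MetricsError:
        lam, r2 = math.nan, math.nan
    if lam and lam > 0 and math.isfinite(lam):
        auc_inf = auc_0_t + float(c[-1]) / lam
        t_half = LN2 / lam
    else:
        auc_inf, t_half = math.nan, math.nan
    return PKMetrics(auc_0_t, auc_inf, cmax, tmax, t_half, lam, r2)


def geometric_mean_ci(
    values: Sequence[float], lo_pct: float = 2.5, hi_pct: float = 97.5
) -> tuple[float, float, float]:
    """Geometric mean with a t-based interval on the log scale.

    The (lo, hi) percent limits are read as a two-sided confidence level
    (default 95%).  With n = 1 the interval degenerates to the point
    value, mirroring single-virtual-subject reporting.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise MetricsError("geometric mean of an empty set")
    if np.any(v <= 0):
        raise MetricsError("geometric mean requires strictly positive values")
    logs = np.log(v)
    gm = float(np.exp(logs.mean()))
    if v.size < 2:
        return gm, gm, gm
    level = (hi_pct - lo_pct) / 100.0
    sem = logs.std(ddof=1) / math.sqrt(v.size)
    tcrit = stats.t.ppf(0.5 + level / 2.0, df=v.size - 1)
    return gm, float(np.exp(logs.mean() - tcrit * sem)), float(
        np.exp(logs.mean() + tcrit * sem)
    )


@dataclass(frozen=True)
class FoldChange:
    ratio: float
    significant: bool


def fold_change_flag(a: float, b: float, threshold: float = 2.0) -> FoldChange:
    """Two-fold significance rule: flag ratios >= threshold (inclusive)."""
    if a <= 0 or b <= 0:
        raise MetricsError("fold change requires positive values")
    ratio = max(a / b, b / a)
    return FoldChange(ratio=ratio, significant=ratio >= threshold)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment correlation of two equal-length series."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise MetricsError("pearson_r needs equal-length series with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise MetricsError("pearson_r undefined for zero-variance input")
    return float(stats.pearsonr(x, y).statistic)
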