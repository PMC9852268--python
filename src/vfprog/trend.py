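"""Trend-based progression labelers: MD slope, VFI slope, pointwise linear
regression (PLR).

Each labeler fits ordinary least squares against time in years since the
first included exam (day resolution) over the whole reliable series and
applies the published decision rule:

* MD slope:  worsening iff slope <= -0.5 dB/yr and two-sided p < 0.05
* VFI slope: worsening iff slope <= -1.8 %/yr and two-sided p < 0.05
* PLR:       per-point OLS on TD at the 52 non-blind-spot locations;
             worsening iff >= 3 locations have slope <= -1 dB/yr and p <= 0.01

Comparison operators follow the printed rules exactly: strict p < 0.05 for
the global slopes, inclusive p <= 0.01 for PLR.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .core import VFSeries, seeing_td

MD_SLOPE_CUTOFF = -0.5     # dB/yr
VFI_SLOPE_CUTOFF = -1.8    # %/yr
PLR_SLOPE_CUTOFF = -1.0    # dB/yr
PLR_P_CUTOFF = 0.01
GLOBAL_P_CUTOFF = 0.05
PLR_MIN_POINTS = 3


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    p_value: float
    n: int


@dataclass(frozen=True)
class ProgressionCall:
    """One method's verdict on one eye, with its supporting trace."""

    method: str
    worsening: bool
    trace: dict = field(default_factory=dict)


def linreg_with_p(times: np.ndarray, values: np.ndarray) -> RegressionResult:
    """OLS slope/intercept with the two-sided t-test p-value on the slope."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    n = times.size
    if n < 3:
        raise ValueError(f"need >= 3 observations for a slope p-value, got {n}")
    if np.ptp(times) == 0:
        raise ValueError("times are all equal; slope undefined")
    res = stats.linregress(times, values)
    return RegressionResult(slope=float(res.slope), intercept=float(res.intercept),
                            p_value=float(res.pvalue), n=n)


def _plr_regressions(series: VFSeries) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised per-point OLS over the 52 seeing locations.

    Returns (slopes, p_values), each length 52.  Closed-form normal
    equations; p from the two-sided t distribution with n-2 df.  Points with
    zero residual variance get p = 0 when the slope is nonzero and p = 1
    when the fit is exactly flat.
    """
    t = series.years()
    n = t.size
    Y = np.array([seeing_td(e) for e in series.exams])  # (n, 52)
    tc = t - t.mean()
    sxx = float(tc @ tc)
    slopes = tc @ (Y - Y.mean(axis=0)) / sxx
    resid = Y - (Y.mean(axis=0) + np.outer(tc, slopes))
    sse = (resid ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(sse / (n - 2) / sxx)
        tstat = np.where(se > 0, slopes / se, np.where(slopes != 0, np.inf, 0.0))
    p = 2 * stats.t.sf(np.abs(tstat), df=n - 2)
    return slopes, p


def md_slope_flag(series: VFSeries) -> ProgressionCall:
    reg = linreg_with_p(series.years(), [e.md for e in series.exams])
    flag = reg.slope <= MD_SLOPE_CUTOFF and reg.p_value < GLOBAL_P_CUTOFF
    return ProgressionCall("md", flag,
                           {"slope": reg.slope, "p_value": reg.p_value, "n": reg.n})


def vfi_slope_flag(series: VFSeries) -> ProgressionCall:
    reg = linreg_with_p(series.years(), [e.vfi for e in series.exams])
    flag = reg.slope <= VFI_SLOPE_CUTOFF and reg.p_value < GLOBAL_P_CUTOFF
    return ProgressionCall("vfi", flag,
                           {"slope": reg.slope, "p_value": reg.p_value, "n": reg.n})


def plr_flag(series: VFSeries) -> ProgressionCall:
    slopes, p = _plr_regressions(series)
    qualifying = np.flatnonzero((slopes <= PLR_SLOPE_CUTOFF) & (p <= PLR_P_CUTOFF))
    flag = qualifying.size >= PLR_MIN_POINTS
    return ProgressionCall("plr", flag,
                           {"qualifying_points": qualifying.tolist(),
                            "n_qualifying": int(qualifying.size),
                            "slopes": slopes, "p_values": p})
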