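"""Windowed coefficient-of-variation statistics and slope inference.

The flow trace is cut into consecutive non-overlapping windows (5 min by
default) anchored at the injection time; each window yields one CV value
(sample standard deviation over mean).  A linear trend in CV versus window
center is tested with ordinary least squares and a two-sided t-test on the
slope, either per subject or pooled across subjects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import ArrayLike, NDArray
from scipy import stats

from dcsflow.cbfi_fitting import CBFiTrace

__all__ = [
    "CVSeries",
    "RegressionResult",
    "PooledRegression",
    "coefficient_of_variation",
    "windowed_cv",
    "windowed_cv_array",
    "fit_cv_slope",
    "pooled_cv_regression",
    "ols_regression",
]


@dataclass(frozen=True)
class CVSeries:
    """Per-window CV values for one subject.

    ``window_center`` is in minutes since the anchor (injection time, or
    record start for sham recordings).
    """

    subject_id: str
    window_center: NDArray[np.float64]
    cv: NDArray[np.float64]
    group: str = ""

    def __post_init__(self) -> None:
        wc = np.asarray(self.window_center, dtype=float)
        cv = np.asarray(self.cv, dtype=float)
        object.__setattr__(self, "window_center", wc)
        object.__setattr__(self, "cv", cv)
        if wc.size != cv.size:
            raise ValueError("window_center and cv must have equal length")
        if wc.size > 1 and np.any(np.diff(wc) <= 0):
            raise ValueError("window_center must be strictly increasing")
        if np.any(cv < 0):
            raise ValueError("cv values must be non-negative")

    def __len__(self) -> int:
        return int(self.cv.size)


@dataclass(frozen=True)
class RegressionResult:
    """OLS slope inference: slope in CV per minute, two-sided t-test p."""

    slope: float
    intercept: float
    slope_se: float
    t_stat: float
    p_value: float
    n_points: int


@dataclass(frozen=True)
class PooledRegression:
    """Pooled fit over all subjects plus the per-subject fit table."""

    pooled: RegressionResult
    per_subject: dict[str, RegressionResult]


def coefficient_of_variation(x: ArrayLike, ddof: int = 1) -> float:
    """CV = s / mean with s the sample (ddof=1) standard deviation."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("CV needs at least 2 samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("CV input contains non-finite values")
    mean = x.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero-mean data")
    return float(x.std(ddof=ddof) / mean)


def windowed_cv_array(
    t: ArrayLike,
    x: ArrayLike,
    window_s: float = 300.0,
    anchor_s: float = 0.0,
    ddof: int = 1,
    subject_id: str = "",
    group: str = "",
) -> CVSeries:
    """Consecutive non-overlapping CV windows of an arbitrary 1-Hz series.

    Windows tile ``[anchor, anchor + window), [anchor + window, ...)``;
    samples before the anchor are ignored and an incomplete trailing window
    is dropped.  Window centers are reported in minutes since the anchor.
    """
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    if t.size != x.size:
        raise ValueError("t and x must have equal length")
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    post = t >= anchor_s
    t_rel = t[post] - anchor_s
    xs = x[post]
    if t_rel.size == 0 or t_rel[-1] + 1.0 < window_s:
        raise ValueError(
            f"series spans {0.0 if t_rel.size == 0 else t_rel[-1] + 1.0:.0f} s "
            f"after the anchor; need at least one full {window_s:.0f} s window"
        )
    idx = np.floor(t_rel / window_s).astype(int)
    n_per = int(round(window_s))  # 1 Hz sampling
    centers, cvs = [], []
    for k in range(idx.max() + 1):
        sel = xs[idx == k]
        sel = sel[np.isfinite(sel)]
        if sel.size < n_per:  # incomplete (trailing or gappy) window
            continue
        centers.append((k + 0.5) * window_s / 60.0)
        cvs.append(coefficient_of_variation(sel, ddof=ddof))
    if not centers:
        raise ValueError("no complete window after the anchor")
    return CVSeries(
        subject_id=subject_id,
        window_center=np.array(centers),
        cv=np.array(cvs),
        group=group,
    )


def windowed_cv(
    trace: CBFiTrace,
    window_s: float = 300.0,
    anchor_s: float = 0.0,
    use_smoothed: bool = True,
    ddof: int = 1,
    subject_id: str = "",
    group: str = "",
) -> CVSeries:
    """Windowed CV of a flow trace (smoothed trace by default)."""
    x = trace.cbfi_smooth if use_smoothed else trace.cbfi
    return windowed_cv_array(
        trace.t, x, window_s=window_s, anchor_s=anchor_s, ddof=ddof,
        subject_id=subject_id, group=group,
    )


def ols_regression(x: ArrayLike, y: ArrayLike) -> RegressionResult:
    """OLS of y on x with a two-sided t-test on the slope."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("regression needs at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("regressor is degenerate (no spread)")
    res = stats.linregress(x, y)
    if res.stderr > 0:
        t_stat = res.slope / res.stderr
    else:
        t_stat = np.inf if res.slope != 0 else 0.0
    p = 2.0 * stats.t.sf(abs(t_stat), df=n - 2) if np.isfinite(t_stat) else 0.0
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        slope_se=float(res.stderr),
        t_stat=float(t_stat),
        p_value=float(p),
        n_points=int(n),
    )


def fit_cv_slope(series: CVSeries) -> RegressionResult:
    """OLS of CV on window center (minutes); two-sided slope t-test."""
    return ols_regression(series.window_center, series.cv)


def pooled_cv_regression(series_list: list[CVSeries]) -> PooledRegression:
    """Pool all (window_center, cv) points across subjects into one OLS fit.

    Points are treated as exchangeable (no per-subject clustering
    correction); per-subject fits are returned alongside.
    """
    if not series_list:
        raise ValueError("no CV series provided")
    x = np.concatenate([s.window_center for s in series_list])
    y = np.concatenate([s.cv for s in series_list])
    pooled = ols_regression(x, y)
    per_subject = {}
    for s in series_list:
        try:
            per_subject[s.subject_id] = fit_cv_slope(s)
        except ValueError:
            continue
    return PooledRegression(pooled=pooled, per_subject=per_subject)
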