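"""Motion-artifact control from 3-axis accelerometer logs.

Probe placement introduces per-axis gains and offsets with no physiological
meaning, so each axis is min-max scaled over the full recording before the
3-D magnitude is formed.  Windowed CV of the magnitude (CV_accel) shares
the flow-CV machinery, and an OLS regression of flow CV on motion CV tests
whether motion explains apparent flow variability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.typing import ArrayLike, NDArray

from dcsflow.variability import CVSeries, RegressionResult, ols_regression, windowed_cv_array

__all__ = [
    "AccelTrace",
    "minmax_scale",
    "accel_magnitude",
    "magnitude_1hz",
    "cv_accel",
    "independence_test",
    "read_accel",
    "write_accel",
]


def minmax_scale(x: ArrayLike) -> NDArray[np.float64]:
    """Scale to [0, 1] as (x - min) / (max - min).

    A constant axis maps to all-zeros with a warning (division-by-zero
    guard); the subsequent CV analysis is unaffected by the choice.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("cannot scale an empty array")
    if x.size < 2:
        raise ValueError("min-max scaling needs at least 2 samples")
    lo, hi = x.min(), x.max()
    if hi == lo:
        warnings.warn("constant axis: min-max scaling maps it to zeros", stacklevel=2)
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


@dataclass(frozen=True)
class AccelTrace:
    """3-axis accelerometer recording with scaled axes and 3-D magnitude."""

    t: NDArray[np.float64]
    ax: NDArray[np.float64]
    ay: NDArray[np.float64]
    az: NDArray[np.float64]
    ax_n: NDArray[np.float64]
    ay_n: NDArray[np.float64]
    az_n: NDArray[np.float64]
    mag: NDArray[np.float64]

    def __post_init__(self) -> None:
        arrays = [self.t, self.ax, self.ay, self.az,
                  self.ax_n, self.ay_n, self.az_n, self.mag]
        sizes = {np.asarray(a).size for a in arrays}
        if len(sizes) != 1:
            raise ValueError("all AccelTrace arrays must share one length")

    @classmethod
    def from_raw(
        cls,
        t: ArrayLike,
        ax: ArrayLike,
        ay: ArrayLike,
        az: ArrayLike,
    ) -> "AccelTrace":
        """Build from raw device-unit axes: scale each axis, form magnitude."""
        t = np.asarray(t, dtype=float)
        ax = np.asarray(ax, dtype=float)
        ay = np.asarray(ay, dtype=float)
        az = np.asarray(az, dtype=float)
        if not (t.size == ax.size == ay.size == az.size):
            raise ValueError("t, ax, ay, az must have equal length")
        axn, ayn, azn = minmax_scale(ax), minmax_scale(ay), minmax_scale(az)
        mag = np.sqrt(axn**2 + ayn**2 + azn**2)
        return cls(t=t, ax=ax, ay=ay, az=az, ax_n=axn, ay_n=ayn, az_n=azn, mag=mag)

    def __len__(self) -> int:
        return int(np.asarray(self.t).size)


def accel_magnitude(trace: AccelTrace) -> NDArray[np.float64]:
    """Pointwise Euclidean norm of the three scaled axes, in [0, sqrt(3)]."""
    a = (np.asarray(trace.ax_n), np.asarray(trace.ay_n), np.asarray(trace.az_n))
    if not (a[0].size == a[1].size == a[2].size):
        raise ValueError("scaled axes must have equal length")
    return np.sqrt(a[0] ** 2 + a[1] ** 2 + a[2] ** 2)


def magnitude_1hz(trace: AccelTrace) -> tuple[NDArray[np.float64], NDArray[np.float64]]:
    """Downsample the magnitude to 1 Hz by per-second windowed means.

    Returns (t_1hz, mag_1hz) with t at whole-second bin starts.
    """
    t = np.asarray(trace.t, dtype=float)
    mag = np.asarray(trace.mag, dtype=float)
    sec = np.floor(t).astype(int)
    sec -= sec.min()
    counts = np.bincount(sec)
    sums = np.bincount(sec, weights=mag)
    present = counts > 0
    t_out = np.flatnonzero(present).astype(float) + np.floor(t.min())
    return t_out, sums[present] / counts[present]


def cv_accel(
    trace: AccelTrace,
    window_s: float = 300.0,
    anchor_s: float = 0.0,
    subject_id: str = "",
    group: str = "",
) -> CVSeries:
    """Windowed CV of the 1-Hz-downsampled 3-D magnitude (CV_accel)."""
    t1, m1 = magnitude_1hz(trace)
    return windowed_cv_array(
        t1, m1, window_s=window_s, anchor_s=anchor_s,
        subject_id=subject_id, group=group,
    )


def independence_test(cv_flow: CVSeries, cv_motion: CVSeries) -> RegressionResult:
    """OLS of flow CV on motion CV over matched windows.

    A non-significant slope supports the claim that motion does not
    explain the observed flow variability.
    """
    if len(cv_flow) != len(cv_motion) or not np.allclose(
        cv_flow.window_center, cv_motion.window_center
    ):
        raise ValueError("flow and motion CV series must share the window grid")
    return ols_regression(cv_motion.cv, cv_flow.cv)


def read_accel(path: str | Path) -> AccelTrace:
    """Read delimited text with header columns (t, x, y, z)."""
    df = pd.read_csv(path)
    required = {"t", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise ValueError(f"accelerometer table must have columns {sorted(required)}")
    return AccelTrace.from_raw(df["t"], df["x"], df["y"], df["z"])


def write_accel(trace: AccelTrace, path: str | Path) -> None:
    pd.DataFrame(
        {"t": trace.t, "x": trace.ax, "y": trace.ay, "z": trace.az}
    ).to_csv(path, index=False)
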