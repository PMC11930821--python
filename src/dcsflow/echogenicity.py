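"""Ultrasound ROI brightness quantification: the echogenicity ratio.

Mean pixel intensity inside an elliptical region of interest, expressed
relative to the corresponding mean in a reference frame (earliest
timepoint, pre-injection, or a control recording).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from numpy.typing import NDArray

__all__ = [
    "EllipseROI",
    "EchoFrame",
    "EchoResult",
    "roi_mask",
    "echogenicity_ratio",
    "load_frame",
]


@dataclass(frozen=True)
class EllipseROI:
    """Elliptical ROI in pixel coordinates (row-major, 0-based).

    Degenerate semi-axes of 0 select only pixel centers lying exactly on
    the corresponding axis line.
    """

    center_row: float
    center_col: float
    semi_axis_row: float
    semi_axis_col: float

    def __post_init__(self) -> None:
        if self.semi_axis_row < 0 or self.semi_axis_col < 0:
            raise ValueError("semi-axes must be non-negative")


@dataclass(frozen=True)
class EchoFrame:
    """One grayscale ultrasound-like frame with its ROI."""

    pixels: NDArray[np.float64]
    roi: EllipseROI
    timestamp_min: float = 0.0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        object.__setattr__(self, "pixels", px)
        if px.ndim != 2:
            raise ValueError("pixels must be a 2-D grayscale grid")
        if np.any(px < 0):
            raise ValueError("pixel intensities must be non-negative")
        nr, nc = px.shape
        r = self.roi
        if (
            r.center_row - r.semi_axis_row < 0
            or r.center_row + r.semi_axis_row > nr - 1
            or r.center_col - r.semi_axis_col < 0
            or r.center_col + r.semi_axis_col > nc - 1
        ):
            raise ValueError("ROI extends outside the image bounds")


@dataclass(frozen=True)
class EchoResult:
    """Echogenicity ratio of one frame against a reference."""

    ratio: float
    pixel_ratio_sd: float | None
    n_pixels: int


def roi_mask(frame: EchoFrame) -> NDArray[np.bool_]:
    """Boolean grid: pixel centers (r, c) with
    ((r - cr)/ar)^2 + ((c - cc)/ac)^2 <= 1."""
    nr, nc = frame.pixels.shape
    r = np.arange(nr)[:, None].astype(float)
    c = np.arange(nc)[None, :].astype(float)
    roi = frame.roi
    with np.errstate(divide="ignore", invalid="ignore"):
        if roi.semi_axis_row > 0:
            term_r = ((r - roi.center_row) / roi.semi_axis_row) ** 2
        else:
            term_r = np.where(r == roi.center_row, 0.0, np.inf)
        if roi.semi_axis_col > 0:
            term_c = ((c - roi.center_col) / roi.semi_axis_col) ** 2
        else:
            term_c = np.where(c == roi.center_col, 0.0, np.inf)
    return term_r + term_c <= 1.0


def _cropped_mask(frame: EchoFrame) -> NDArray[np.bool_]:
    mask = roi_mask(frame)
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    return mask[rows[0]: rows[-1] + 1, cols[0]: cols[-1] + 1]


def echogenicity_ratio(frame: EchoFrame, reference: EchoFrame) -> EchoResult:
    """Ratio of ROI mean intensities: frame over reference.

    ``pixel_ratio_sd`` — the sample standard deviation of per-pixel
    intensity ratios — is reported only when the two ROI masks are
    congruent (identical cropped patterns), since per-pixel pairing is
    otherwise undefined.
    """
    mask_f = roi_mask(frame)
    mask_r = roi_mask(reference)
    if not mask_f.any() or not mask_r.any():
        raise ValueError("ROI mask is empty")
    mean_f = float(frame.pixels[mask_f].mean())
    mean_r = float(reference.pixels[mask_r].mean())
    if mean_r == 0:
        raise ValueError("reference ROI mean is zero; ratio undefined")
    ratio = mean_f / mean_r

    pixel_ratio_sd = None
    crop_f, crop_r = _cropped_mask(frame), _cropped_mask(reference)
    if crop_f.shape == crop_r.shape and np.array_equal(crop_f, crop_r):
        vf = frame.pixels[mask_f]
        vr = reference.pixels[mask_r]
        with np.errstate(divide="ignore", invalid="ignore"):
            per_pixel = vf / vr
        per_pixel = per_pixel[np.isfinite(per_pixel)]
        if per_pixel.size >= 2:
            pixel_ratio_sd = float(per_pixel.std(ddof=1))
    return EchoResult(
        ratio=ratio, pixel_ratio_sd=pixel_ratio_sd, n_pixels=int(mask_f.sum())
    )


def load_frame(
    path: str | Path, roi: EllipseROI, timestamp_min: float = 0.0
) -> EchoFrame:
    """Load a PNG/TIFF grayscale image as an EchoFrame.

    RGB(A) inputs are converted by channel averaging; intensities are
    treated as linear.
    """
    import imageio.v3 as iio

    px = np.asarray(iio.imread(path), dtype=float)
    if px.ndim == 3:
        px = px[..., :3].mean(axis=2)
    return EchoFrame(pixels=px, roi=roi, timestamp_min=timestamp_min)
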