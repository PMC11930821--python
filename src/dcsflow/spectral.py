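"""Normalized low-frequency power spectra of flow traces.

Welch periodogram (500-s Hann segments, 50% overlap, per-segment linear
detrend) of the 1-Hz flow index, restricted to a band (0.002-0.4 Hz by
default) and normalized to unit total in-band power, plus the pointwise
across-subject average.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import NDArray
from scipy import signal

from dcsflow.cbfi_fitting import CBFiTrace

__all__ = ["Spectrum", "cbfi_spectrum", "average_spectra"]


@dataclass(frozen=True)
class Spectrum:
    """Band-restricted normalized power spectrum of one subject.

    ``power`` is the unnormalized Welch power density (kept for variance
    cross-checks); ``power_norm`` sums to 1 over the band.
    """

    freq: NDArray[np.float64]
    power_norm: NDArray[np.float64]
    subject_id: str = ""
    power: NDArray[np.float64] | None = None

    def __post_init__(self) -> None:
        f = np.asarray(self.freq, dtype=float)
        p = np.asarray(self.power_norm, dtype=float)
        object.__setattr__(self, "freq", f)
        object.__setattr__(self, "power_norm", p)
        if f.size != p.size:
            raise ValueError("freq and power_norm must have equal length")
        if np.any(p < 0):
            raise ValueError("power must be non-negative")
        if p.size and abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("power_norm must sum to 1")


def cbfi_spectrum(
    trace: CBFiTrace,
    band: tuple[float, float] = (0.002, 0.4),
    fs: float = 1.0,
    nperseg: int = 500,
    use_smoothed: bool = False,
    subject_id: str = "",
) -> Spectrum:
    """Normalized in-band Welch spectrum of a 1-Hz flow trace.

    The raw (unsmoothed) trace is used by default: the 8-sample moving
    mean has spectral nulls at multiples of 0.125 Hz that would distort
    the in-band shape.

    Raises
    ------
    ValueError
        If the trace is shorter than the minimum duration needed to
        resolve the low band edge, or has no in-band variance.
    """
    f_lo, f_hi = band
    if not (0 < f_lo < f_hi <= fs / 2):
        raise ValueError("band must satisfy 0 < f_lo < f_hi <= Nyquist")
    x = trace.cbfi_smooth if use_smoothed else trace.cbfi
    x = np.asarray(x, dtype=float)
    ok = np.isfinite(x)
    if not ok.all():
        x = x.copy()
        x[~ok] = np.nanmean(x)
    min_dur = max(nperseg / fs, 1.0 / f_lo)
    duration = x.size / fs
    if duration < min_dur:
        raise ValueError(
            f"trace duration {duration:.0f} s is below the {min_dur:.0f} s "
            f"minimum required to resolve {f_lo} Hz"
        )
    if np.ptp(x) == 0:
        raise ValueError("trace has no in-band variance; spectrum undefined")
    x = signal.detrend(x, type="linear")
    freq, pxx = signal.welch(
        x,
        fs=fs,
        window="hann",
        nperseg=min(nperseg, x.size),
        noverlap=min(nperseg, x.size) // 2,
        detrend="linear",
    )
    in_band = (freq >= f_lo) & (freq <= f_hi)
    freq, pxx = freq[in_band], pxx[in_band]
    total = pxx.sum()
    if total <= 0 or not np.isfinite(total):
        raise ValueError("trace has no in-band variance; spectrum undefined")
    return Spectrum(
        freq=freq, power_norm=pxx / total, subject_id=subject_id, power=pxx
    )


def average_spectra(spectra: list[Spectrum]) -> Spectrum:
    """Pointwise mean of same-grid spectra, renormalized to unit sum."""
    if not spectra:
        raise ValueError("no spectra to average")
    f0 = spectra[0].freq
    for s in spectra[1:]:
        if s.freq.size != f0.size or not np.allclose(s.freq, f0):
            raise ValueError("spectra must share one frequency grid")
    mean = np.mean([s.power_norm for s in spectra], axis=0)
    return Spectrum(freq=f0, power_norm=mean / mean.sum(), subject_id="average")


def band_power_fraction(spectrum: Spectrum, f_cut: float) -> float:
    """Fraction of normalized in-band power at frequencies <= f_cut."""
    return float(spectrum.power_norm[spectrum.freq <= f_cut].sum())
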