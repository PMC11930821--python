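"""Synthetic session generator: every input the pipeline consumes.

Produces flow-index time series with band-limited low-frequency
fluctuations whose amplitude ramps after a simulated injection event,
noisy g2 curves through the forward model, motion traces statistically
independent of flow, a viscosity-controlled Brownian phantom, and
speckle-like image series with a brightening ventricular ROI.

All randomness flows through ``numpy.random.default_rng``; flow, motion
and imaging draw from independent child streams spawned from one seed, so
any one output is reproducible and independent of the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.typing import NDArray

from dcsflow.accelerometry import AccelTrace
from dcsflow.cbfi_fitting import CorrelationCurve
from dcsflow.diffusion_model import OpticalConfig, default_lag_grid
from dcsflow.echogenicity import EchoFrame, EllipseROI, roi_mask

__all__ = [
    "ScenarioConfig",
    "PhantomConfig",
    "AccelProfile",
    "simulate_bfi_timeseries",
    "emit_correlation_curves",
    "emit_curve_matrix",
    "simulate_phantom",
    "phantom_bfi",
    "simulate_accel",
    "simulate_echo_series",
    "band_limited_noise",
]


@dataclass(frozen=True)
class AccelProfile:
    """Motion generator parameters (per-axis random walk + jitter)."""

    fs: float = 25.0
    drift_sigma: float = 0.02
    jitter_sigma: float = 0.05
    gains: tuple[float, float, float] = (1.0, 1.0, 1.0)
    offsets: tuple[float, float, float] = (0.0, 0.0, 0.0)


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of one synthetic recording session.

    The flow index fluctuates within ``fluct_band`` with an amplitude that
    ramps linearly from ``cv_start`` (held during the pre-injection
    baseline) to ``cv_end`` at the end of the record.
    """

    seed: int = 0
    duration_s: float = 3900.0
    baseline_s: float = 300.0
    bfi_baseline: float = 1e-8
    fluct_band: tuple[float, float] = (0.01, 0.25)
    cv_start: float = 0.05
    cv_end: float = 0.05
    g2_noise_sigma: float = 0.02
    beta_true: float = 0.5
    accel_profile: AccelProfile = field(default_factory=AccelProfile)

    def __post_init__(self) -> None:
        if not (0 <= self.cv_start <= self.cv_end < 1):
            raise ValueError("need 0 <= cv_start <= cv_end < 1")
        if self.fluct_band[1] > 0.5:
            raise ValueError("fluct_band upper edge exceeds the 0.5 Hz Nyquist at 1 Hz")
        if not (0 < self.baseline_s <= self.duration_s):
            raise ValueError("need 0 < baseline_s <= duration_s")
        if self.bfi_baseline <= 0:
            raise ValueError("bfi_baseline must be positive")


@dataclass(frozen=True)
class PhantomConfig:
    """Viscosity-controlled Brownian phantom (constant temperature)."""

    viscosity_ref: float = 1.0e-3
    viscosity: float = 1.0e-3
    db_ref: float = 1.0e-8

    def __post_init__(self) -> None:
        if self.viscosity_ref <= 0 or self.viscosity <= 0:
            raise ValueError("viscosities must be strictly positive")
        if self.db_ref <= 0:
            raise ValueError("db_ref must be strictly positive")


def band_limited_noise(
    n: int, band: tuple[float, float], fs: float, rng: np.random.Generator
) -> NDArray[np.float64]:
    """Unit-variance Gaussian noise band-limited by FFT-domain masking.

    White Gaussian noise is transformed, bins outside ``band`` are zeroed,
    and the inverse transform is rescaled to unit sample variance.
    """
    f_lo, f_hi = band
    if not (0 <= f_lo < f_hi <= fs / 2):
        raise ValueError("band must satisfy 0 <= f_lo < f_hi <= Nyquist")
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freq = np.fft.rfftfreq(n, d=1.0 / fs)
    spec[(freq < f_lo) | (freq > f_hi)] = 0.0
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    if sd == 0:
        raise ValueError("band contains no FFT bins for this record length")
    return x / sd


def simulate_bfi_timeseries(
    cfg: ScenarioConfig, rng: np.random.Generator | None = None
) -> tuple[NDArray[np.float64], NDArray[np.float64]]:
    """True flow index at 1 Hz: baseline * (1 + a(t) * z(t)).

    ``z`` is unit-variance band-limited noise; ``a`` holds at ``cv_start``
    through the baseline and ramps linearly to ``cv_end`` at the end of
    the record.  Values are clipped below at baseline/10.

    Returns (t_seconds, bfi).
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(1)[0])
    n = int(round(cfg.duration_s))
    t = np.arange(n, dtype=float)
    if cfg.cv_end == 0:
        return t, np.full(n, cfg.bfi_baseline)
    z = band_limited_noise(n, cfg.fluct_band, fs=1.0, rng=rng)
    a = np.full(n, cfg.cv_start)
    ramp = t >= cfg.baseline_s
    span = max(cfg.duration_s - cfg.baseline_s, 1.0)
    a[ramp] = cfg.cv_start + (cfg.cv_end - cfg.cv_start) * (
        (t[ramp] - cfg.baseline_s) / span
    )
    bfi = cfg.bfi_baseline * (1.0 + a * z)
    return t, np.clip(bfi, cfg.bfi_baseline / 10.0, None)


def emit_curve_matrix(
    bfi_t: NDArray[np.float64],
    optics: OpticalConfig,
    beta_true: float = 0.5,
    g2_noise_sigma: float = 0.0,
    seed: int | np.random.Generator = 0,
    tau: NDArray[np.float64] | None = None,
) -> tuple[NDArray[np.float64], NDArray[np.float64]]:
    """Noisy g2 curves for a flow series, as a (n_times, n_lags) matrix.

    Noise is multiplicative on the decaying part:
    ``g2_obs = 1 + (g2 - 1) * (1 + eps)``, eps iid N(0, sigma^2) per lag.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(np.random.SeedSequence(seed).spawn(2)[1])
    )
    if tau is None:
        tau = default_lag_grid()
    bfi_t = np.asarray(bfi_t, dtype=float)
    # one model evaluation per unique flow value would not vectorize well;
    # the model itself broadcasts over (n_times, n_lags)
    from dcsflow.diffusion_model import _g1_unnormalized, derive_geometry

    geom = derive_geometry(optics)
    den = _g1_unnormalized(np.zeros(1), 0.0, optics, geom)[0]
    g1 = _g1_unnormalized(tau, bfi_t, optics, geom) / den
    decay = beta_true * g1**2
    if g2_noise_sigma > 0:
        decay = decay * (1.0 + g2_noise_sigma * rng.standard_normal(decay.shape))
    return tau, 1.0 + decay


def emit_correlation_curves(
    bfi_t: NDArray[np.float64],
    optics: OpticalConfig,
    beta_true: float = 0.5,
    g2_noise_sigma: float = 0.0,
    seed: int | np.random.Generator = 0,
    tau: NDArray[np.float64] | None = None,
    t: NDArray[np.float64] | None = None,
) -> list[CorrelationCurve]:
    """One CorrelationCurve per second from the forward model plus noise."""
    tau, g2 = emit_curve_matrix(
        bfi_t, optics, beta_true=beta_true, g2_noise_sigma=g2_noise_sigma,
        seed=seed, tau=tau,
    )
    if t is None:
        t = np.arange(len(bfi_t), dtype=float)
    return [
        CorrelationCurve(t_acq=float(ti), tau=tau, g2=row)
        for ti, row in zip(t, g2)
    ]


def phantom_bfi(cfg: PhantomConfig) -> float:
    """Stokes-Einstein scaling: db = db_ref * viscosity_ref / viscosity."""
    return cfg.db_ref * cfg.viscosity_ref / cfg.viscosity


def simulate_phantom(
    cfg: PhantomConfig,
    optics: OpticalConfig,
    duration_s: float = 1200.0,
    beta_true: float = 0.5,
    g2_noise_sigma: float = 0.02,
    seed: int = 0,
    accel_profile: AccelProfile | None = None,
    tau: NDArray[np.float64] | None = None,
) -> tuple[float, list[CorrelationCurve], AccelTrace]:
    """Stationary phantom record at one viscosity plus independent motion.

    Returns (effective bfi, g2 curves, accelerometer trace).
    """
    db = phantom_bfi(cfg)
    ss = np.random.SeedSequence(seed).spawn(2)
    n = int(round(duration_s))
    curves = emit_correlation_curves(
        np.full(n, db), optics, beta_true=beta_true,
        g2_noise_sigma=g2_noise_sigma, seed=np.random.default_rng(ss[0]), tau=tau,
    )
    accel = simulate_accel(
        duration_s, accel_profile or AccelProfile(), rng=np.random.default_rng(ss[1])
    )
    return db, curves, accel


def simulate_accel(
    duration_s: float,
    profile: AccelProfile | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> AccelTrace:
    """Per-axis random-walk drift + Gaussian jitter, then gain/offset.

    Uses an RNG stream separate from the flow generator so motion is
    statistically independent of flow by construction.
    """
    profile = profile or AccelProfile()
    if rng is None:
        seed_seq = np.random.SeedSequence(0 if seed is None else seed).spawn(3)
        rng = np.random.default_rng(seed_seq[2])
    n = int(round(duration_s * profile.fs))
    t = np.arange(n) / profile.fs
    axes = []
    for gain, offset in zip(profile.gains, profile.offsets):
        drift = np.cumsum(rng.standard_normal(n) * profile.drift_sigma)
        jitter = rng.standard_normal(n) * profile.jitter_sigma
        axes.append(gain * (drift + jitter) + offset)
    return AccelTrace.from_raw(t, *axes)


def simulate_echo_series(
    n_frames: int,
    roi: EllipseROI,
    brightening_schedule: Sequence[float],
    shape: tuple[int, int] = (128, 128),
    background_mean: float = 20.0,
    roi_base_mean: float = 40.0,
    speckle_shape: float = 4.0,
    frame_interval_min: float = 10.0,
    seed: int | np.random.Generator = 0,
) -> list[EchoFrame]:
    """Speckle-like frames whose ROI mean follows a brightening schedule.

    Pixels are iid gamma-distributed (shape ``speckle_shape``); inside the
    ROI the gamma scale is raised so the ROI mean equals
    ``roi_base_mean * schedule[i]``.
    """
    if len(brightening_schedule) != n_frames:
        raise ValueError("brightening_schedule length must equal n_frames")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(np.random.SeedSequence(seed).spawn(4)[3])
    )
    template = EchoFrame(pixels=np.zeros(shape), roi=roi)
    mask = roi_mask(template)
    frames = []
    for i, factor in enumerate(brightening_schedule):
        px = rng.gamma(speckle_shape, background_mean / speckle_shape, size=shape)
        px[mask] = rng.gamma(
            speckle_shape,
            roi_base_mean * factor / speckle_shape,
            size=int(mask.sum()),
        )
        frames.append(
            EchoFrame(pixels=px, roi=roi, timestamp_min=i * frame_interval_min)
        )
    return frames
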