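"""Forward model for DCS on a semi-infinite homogeneous turbid medium.

Closed-form field autocorrelation g1(tau) for a point source and detector on
the surface of a semi-infinite medium with an extrapolated (partial-current)
boundary, Brownian scatterer dynamics with mean-square displacement
``<dr^2(tau)> = 6 * bfi * tau``, and the Siegert relation for the intensity
autocorrelation g2(tau).

Units: lengths in cm, lags in s, blood flow index (bfi) in cm^2/s.  The
source wavelength is specified in nm and converted internally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.typing import ArrayLike, NDArray

__all__ = [
    "OpticalConfig",
    "ModelGeometry",
    "FlowState",
    "InvalidConfigError",
    "derive_geometry",
    "effective_reflection_coefficient",
    "g1_model",
    "g2_model",
    "default_lag_grid",
]

NM_PER_CM = 1.0e7


class InvalidConfigError(ValueError):
    """Raised for non-physical optical or model configuration."""


@dataclass(frozen=True)
class OpticalConfig:
    """Optical and geometric constants of a DCS measurement.

    Parameters
    ----------
    mu_a : float
        Absorption coefficient, cm^-1.
    mu_s_prime : float
        Reduced scattering coefficient, cm^-1.
    wavelength : float
        Source wavelength, nm.
    n_medium : float
        Tissue refractive index (outside medium assumed n = 1).
    rho : float
        Source-detector separation on the surface, cm.
    """

    mu_a: float = 0.1
    mu_s_prime: float = 8.0
    wavelength: float = 785.0
    n_medium: float = 1.4
    rho: float = 0.5

    def __post_init__(self) -> None:
        for name in ("mu_a", "mu_s_prime", "wavelength", "n_medium", "rho"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise InvalidConfigError(
                    f"{name} must be strictly positive and finite, got {value!r}"
                )
        if self.mu_s_prime / self.mu_a < 10:
            warnings.warn(
                "mu_s_prime / mu_a < 10: diffusion approximation is questionable",
                stacklevel=2,
            )
        if self.rho <= 1.0 / self.mu_s_prime:
            raise InvalidConfigError(
                f"rho = {self.rho} cm must exceed one transport mean free path "
                f"1/mu_s_prime = {1.0 / self.mu_s_prime:.4g} cm"
            )

    @property
    def wavelength_cm(self) -> float:
        return self.wavelength / NM_PER_CM


@dataclass(frozen=True)
class ModelGeometry:
    """Derived boundary-condition bookkeeping for the semi-infinite solution.

    Attributes
    ----------
    z0 : float
        Depth of the effective isotropic source, 1/mu_s_prime, cm.
    zb : float
        Extrapolated boundary distance, cm.
    r1 : float
        Distance from the effective source to the detector, cm.
    rb : float
        Distance from the negative image source to the detector, cm.
    k0 : float
        In-medium optical wavenumber 2*pi*n_medium/lambda, cm^-1.
    r_eff : float
        Effective (internal) reflection coefficient of the boundary.
    """

    z0: float
    zb: float
    r1: float
    rb: float
    k0: float
    r_eff: float

    def __post_init__(self) -> None:
        if not (self.rb > self.r1 > 0):
            raise InvalidConfigError("geometry requires rb > r1 > 0")
        if self.zb <= 0:
            raise InvalidConfigError("zb must be positive")
        if not (0 <= self.r_eff < 1):
            raise InvalidConfigError("r_eff must lie in [0, 1)")


@dataclass(frozen=True)
class FlowState:
    """Dynamic state of the scatterers: flow index and coherence factor."""

    bfi: float
    beta: float = 0.5

    def __post_init__(self) -> None:
        if not np.isfinite(self.bfi) or self.bfi < 0:
            raise InvalidConfigError(f"bfi must be >= 0, got {self.bfi!r}")
        if not (0 < self.beta <= 1):
            raise InvalidConfigError(f"beta must lie in (0, 1], got {self.beta!r}")


def effective_reflection_coefficient(n_relative: float) -> float:
    """Effective reflection coefficient from the standard polynomial fit.

    ``R_eff = -1.440/n^2 + 0.710/n + 0.668 + 0.0636*n`` in the relative
    refractive index ``n = n_medium / n_outside``.  Clipped below at 0 (the
    fit is slightly negative for n just under 1).
    """
    n = float(n_relative)
    if n <= 0:
        raise InvalidConfigError("relative refractive index must be positive")
    r_eff = -1.440 / n**2 + 0.710 / n + 0.668 + 0.0636 * n
    return max(r_eff, 0.0)


def derive_geometry(optics: OpticalConfig) -> ModelGeometry:
    """Boundary-condition geometry for the extrapolated-boundary solution."""
    z0 = 1.0 / optics.mu_s_prime
    r_eff = effective_reflection_coefficient(optics.n_medium)
    zb = 2.0 * (1.0 + r_eff) / (3.0 * optics.mu_s_prime * (1.0 - r_eff))
    r1 = float(np.hypot(optics.rho, z0))
    rb = float(np.hypot(optics.rho, z0 + 2.0 * zb))
    k0 = 2.0 * np.pi * optics.n_medium / optics.wavelength_cm
    return ModelGeometry(z0=z0, zb=zb, r1=r1, rb=rb, k0=k0, r_eff=r_eff)


def _check_tau(tau: ArrayLike) -> NDArray[np.float64]:
    tau = np.asarray(tau, dtype=float)
    if tau.ndim != 1:
        raise ValueError("tau must be one-dimensional")
    if tau.size == 0:
        raise ValueError("tau must be non-empty")
    if np.any(~np.isfinite(tau)) or np.any(tau < 0):
        raise ValueError("lags must be finite and non-negative")
    if np.any(np.diff(tau) < 0):
        raise ValueError("lags must be sorted ascending")
    return tau


def _g1_unnormalized(
    tau: NDArray[np.float64], bfi: ArrayLike, optics: OpticalConfig, geom: ModelGeometry
) -> NDArray[np.float64]:
    # K(tau)^2 = 3 mu_a mu_s' + mu_s'^2 k0^2 <dr^2> with <dr^2> = 6 bfi tau
    k_sq = (
        3.0 * optics.mu_a * optics.mu_s_prime
        + 6.0 * optics.mu_s_prime**2 * geom.k0**2 * np.multiply.outer(bfi, tau)
    )
    k = np.sqrt(k_sq)
    return np.exp(-k * geom.r1) / geom.r1 - np.exp(-k * geom.rb) / geom.rb


def g1_model(
    tau: ArrayLike, flow: FlowState, optics: OpticalConfig
) -> NDArray[np.float64]:
    """Normalized field autocorrelation g1(tau).

    ``g1(tau) = [exp(-K r1)/r1 - exp(-K rb)/rb] / [same at tau = 0]`` with
    ``K(tau) = sqrt(3 mu_a mu_s' + 6 mu_s'^2 k0^2 bfi tau)``.

    Parameters
    ----------
    tau : array_like
        Lags in seconds, non-negative, sorted ascending.
    flow : FlowState
        Flow index (cm^2/s); ``beta`` is ignored here.
    optics : OpticalConfig

    Returns
    -------
    ndarray
        g1 values in (0, 1], with g1(0) = 1.
    """
    tau = _check_tau(tau)
    geom = derive_geometry(optics)
    num = _g1_unnormalized(tau, flow.bfi, optics, geom)
    den = _g1_unnormalized(np.zeros(1), 0.0, optics, geom)[0]
    return num / den


def g2_model(
    tau: ArrayLike, flow: FlowState, optics: OpticalConfig
) -> NDArray[np.float64]:
    """Intensity autocorrelation via the Siegert relation, g2 = 1 + beta*g1^2."""
    g1 = g1_model(tau, flow, optics)
    return 1.0 + flow.beta * g1**2


def default_lag_grid(
    lo: float = 1e-7, hi: float = 1e-1, points_per_decade: int = 64
) -> NDArray[np.float64]:
    """Multi-tau-style logarithmic lag grid (hardware-correlator-like)."""
    if not (0 < lo < hi):
        raise ValueError("need 0 < lo < hi")
    if points_per_decade < 1:
        raise ValueError("points_per_decade must be >= 1")
    decades = np.log10(hi / lo)
    n = int(round(decades * points_per_decade)) + 1
    return np.logspace(np.log10(lo), np.log10(hi), n)
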