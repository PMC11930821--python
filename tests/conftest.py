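import numpy as np
import pytest

from dcsflow.diffusion_model import FlowState, OpticalConfig, default_lag_grid, g2_model
from dcsflow.cbfi_fitting import CorrelationCurve


@pytest.fixture(scope="session")
def optics() -> OpticalConfig:
    """Measurement constants of the target protocol."""
    return OpticalConfig(mu_a=0.1, mu_s_prime=8.0, wavelength=785.0,
                         n_medium=1.4, rho=0.5)


@pytest.fixture(scope="session")
def lag_grid():
    return default_lag_grid(points_per_decade=32)


@pytest.fixture
def make_curve(optics, lag_grid):
    """Factory for noiseless synthetic curves from the forward model."""

    def _make(bfi=1e-8, beta=0.5, t_acq=0.0, tau=None):
        tau = lag_grid if tau is None else tau
        g2 = g2_model(tau, FlowState(bfi=bfi, beta=beta), optics)
        return CorrelationCurve(t_acq=t_acq, tau=tau, g2=g2)

    return _make
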