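import numpy as np
import pytest

from dcsflow.cbfi_fitting import fit_trace
from dcsflow.diffusion_model import FlowState, g2_model
from dcsflow.echogenicity import EllipseROI, echogenicity_ratio
from dcsflow.spectral import cbfi_spectrum
from dcsflow.synthetic import (
    AccelProfile,
    PhantomConfig,
    ScenarioConfig,
    band_limited_noise,
    emit_correlation_curves,
    emit_curve_matrix,
    phantom_bfi,
    simulate_accel,
    simulate_bfi_timeseries,
    simulate_echo_series,
    simulate_phantom,
)


class TestScenarioConfig:
    def test_cv_ordering_enforced(self):
        with pytest.raises(ValueError):
            ScenarioConfig(cv_start=0.3, cv_end=0.1)

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            ScenarioConfig(fluct_band=(0.01, 0.6))


class TestBandLimitedNoise:
    def test_unit_variance(self):
        rng = np.random.default_rng(0)
        z = band_limited_noise(4096, (0.01, 0.25), 1.0, rng)
        assert z.std() == pytest.approx(1.0, abs=1e-12)

    def test_power_concentrated_in_band(self):
        rng = np.random.default_rng(1)
        z = band_limited_noise(8192, (0.01, 0.25), 1.0, rng)
        spec = np.abs(np.fft.rfft(z)) ** 2
        freq = np.fft.rfftfreq(8192)
        in_band = (freq >= 0.01) & (freq <= 0.25)
        assert spec[in_band].sum() / spec.sum() > 0.999

    def test_empty_band_rejected(self):
        rng = np.random.default_rng(2)
        with pytest.raises(ValueError, match="bins"):
            band_limited_noise(16, (0.001, 0.002), 1.0, rng)


class TestSimulateBfi:
    def test_zero_cv_is_constant(self):
        cfg = ScenarioConfig(seed=1, duration_s=600, cv_start=0.0, cv_end=0.0)
        t, bfi = simulate_bfi_timeseries(cfg)
        np.testing.assert_array_equal(bfi, cfg.bfi_baseline)
        assert t.size == 600

    def test_stationary_cv_recovered(self):
        cfg = ScenarioConfig(
            seed=2, duration_s=7200, baseline_s=300, cv_start=0.1, cv_end=0.1
        )
        _, bfi = simulate_bfi_timeseries(cfg)
        assert bfi.std() / bfi.mean() == pytest.approx(0.1, rel=0.10)

    def test_deterministic_given_seed(self):
        cfg = ScenarioConfig(seed=3, duration_s=600, cv_start=0.05, cv_end=0.2)
        _, a = simulate_bfi_timeseries(cfg)
        _, b = simulate_bfi_timeseries(cfg)
        np.testing.assert_array_equal(a, b)

    def test_ramp_raises_late_variability(self):
        cfg = ScenarioConfig(
            seed=4, duration_s=3900, baseline_s=300, cv_start=0.02, cv_end=0.3
        )
        _, bfi = simulate_bfi_timeseries(cfg)
        early = bfi[300:900]
        late = bfi[3300:3900]
        assert late.std() / late.mean() > 2 * early.std() / early.mean()

    def test_positivity_clip(self):
        cfg = ScenarioConfig(
            seed=5, duration_s=3600, baseline_s=60, cv_start=0.8, cv_end=0.8
        )
        _, bfi = simulate_bfi_timeseries(cfg)
        assert bfi.min() >= cfg.bfi_baseline / 10.0

    def test_spectral_fidelity(self):
        from dcsflow.cbfi_fitting import CBFiTrace

        cfg = ScenarioConfig(
            seed=6, duration_s=3600, baseline_s=300, cv_start=0.1, cv_end=0.1,
            fluct_band=(0.01, 0.25),
        )
        t, bfi = simulate_bfi_timeseries(cfg)
        trace = CBFiTrace(t=t, cbfi=bfi, cbfi_smooth=bfi)
        spec = cbfi_spectrum(trace, band=(0.002, 0.4))
        in_band = (spec.freq >= 0.01) & (spec.freq <= 0.26)
        assert spec.power_norm[in_band].sum() >= 0.90


class TestEmitCurves:
    def test_noiseless_reproduces_model(self, optics, lag_grid):
        bfi_t = np.array([1e-8, 2e-8])
        tau, g2 = emit_curve_matrix(bfi_t, optics, beta_true=0.5, tau=lag_grid)
        for b, row in zip(bfi_t, g2):
            np.testing.assert_allclose(
                row, g2_model(tau, FlowState(bfi=b, beta=0.5), optics), rtol=1e-12
            )

    def test_noiseless_round_trip_through_fit(self, optics, lag_grid):
        rng = np.random.default_rng(7)
        bfi_t = 1e-8 * (1 + 0.1 * rng.standard_normal(20))
        curves = emit_correlation_curves(bfi_t, optics, beta_true=0.5, tau=lag_grid)
        trace = fit_trace(curves, optics)
        np.testing.assert_allclose(trace.cbfi, bfi_t, rtol=1e-6)

    def test_noisy_fit_unbiased(self, optics, lag_grid):
        bfi = 1e-8
        tau, g2 = emit_curve_matrix(
            np.full(600, bfi), optics, beta_true=0.5,
            g2_noise_sigma=0.02, seed=8, tau=lag_grid,
        )
        from dcsflow.cbfi_fitting import fit_curve_matrix

        bfi_hat, _, _ = fit_curve_matrix(tau, g2, optics)
        assert abs(bfi_hat.mean() - bfi) < 0.01 * bfi

    def test_deterministic_given_seed(self, optics, lag_grid):
        _, a = emit_curve_matrix(np.full(5, 1e-8), optics,
                                 g2_noise_sigma=0.05, seed=9, tau=lag_grid)
        _, b = emit_curve_matrix(np.full(5, 1e-8), optics,
                                 g2_noise_sigma=0.05, seed=9, tau=lag_grid)
        np.testing.assert_array_equal(a, b)


class TestPhantom:
    def test_reference_viscosity_identity(self):
        cfg = PhantomConfig(viscosity_ref=1e-3, viscosity=1e-3, db_ref=1e-8)
        assert phantom_bfi(cfg) == 1e-8

    def test_double_viscosity_halves_fitted_bfi(self, optics, lag_grid):
        fitted = {}
        for factor in (1.0, 2.0):
            cfg = PhantomConfig(viscosity_ref=1e-3, viscosity=factor * 1e-3,
                                db_ref=1e-8)
            db, curves, _ = simulate_phantom(
                cfg, optics, duration_s=30, g2_noise_sigma=0.0, seed=10, tau=lag_grid
            )
            trace = fit_trace(curves, optics)
            fitted[factor] = trace.cbfi.mean()
        assert fitted[2.0] / fitted[1.0] == pytest.approx(0.5, rel=0.02)

    def test_zero_viscosity_rejected(self):
        with pytest.raises(ValueError):
            PhantomConfig(viscosity=0.0)

    def test_motion_independent_of_flow(self, optics, lag_grid):
        _, _, accel_a = simulate_phantom(
            PhantomConfig(viscosity=1e-3), optics, duration_s=30,
            seed=11, tau=lag_grid,
        )
        _, _, accel_b = simulate_phantom(
            PhantomConfig(viscosity=2e-3), optics, duration_s=30,
            seed=11, tau=lag_grid,
        )
        # same seed, different viscosity: motion stream is untouched
        np.testing.assert_array_equal(accel_a.mag, accel_b.mag)


class TestSimulateAccel:
    def test_deterministic(self):
        a = simulate_accel(60, seed=12)
        b = simulate_accel(60, seed=12)
        np.testing.assert_array_equal(a.mag, b.mag)

    def test_zero_motion_constant_axes_warn(self):
        profile = AccelProfile(drift_sigma=0.0, jitter_sigma=0.0)
        with pytest.warns(UserWarning, match="constant axis"):
            trace = simulate_accel(10, profile=profile, seed=13)
        np.testing.assert_array_equal(trace.mag, 0.0)

    def test_gain_offset_invariance_of_magnitude(self):
        base = simulate_accel(120, profile=AccelProfile(), seed=14)
        transformed = simulate_accel(
            120,
            profile=AccelProfile(gains=(10.0, 1.0, 1.0), offsets=(3.0, 0.0, 0.0)),
            seed=14,
        )
        np.testing.assert_allclose(transformed.mag, base.mag, atol=1e-9)

    def test_sampling_rate(self):
        trace = simulate_accel(10, profile=AccelProfile(fs=25.0), seed=15)
        assert len(trace) == 250


class TestSimulateEchoSeries:
    ROI = EllipseROI(64, 64, 24, 32)

    def test_schedule_length_enforced(self):
        with pytest.raises(ValueError, match="length"):
            simulate_echo_series(3, self.ROI, [1.0, 2.0], seed=16)

    def test_flat_schedule_unit_ratios(self):
        frames = simulate_echo_series(4, self.ROI, [1.0] * 4, seed=17)
        for frame in frames[1:]:
            res = echogenicity_ratio(frame, frames[0])
            assert res.ratio == pytest.approx(1.0, abs=0.05)

    def test_brightening_schedule_recovered(self):
        schedule = [1.0, 1.5, 2.8]
        frames = simulate_echo_series(3, self.ROI, schedule, seed=18)
        for factor, frame in zip(schedule, frames):
            res = echogenicity_ratio(frame, frames[0])
            assert res.ratio == pytest.approx(factor, rel=0.05)

    def test_small_roi_noisier_than_large(self):
        small = EllipseROI(64, 64, 2, 2)
        large = EllipseROI(64, 64, 30, 30)
        ratios = {"small": [], "large": []}
        for seed in range(25):
            for name, roi in (("small", small), ("large", large)):
                frames = simulate_echo_series(2, roi, [1.0, 1.0], seed=100 + seed)
                ratios[name].append(
                    echogenicity_ratio(frames[1], frames[0]).ratio
                )
        assert np.var(ratios["small"]) > np.var(ratios["large"])

    def test_deterministic(self):
        a = simulate_echo_series(2, self.ROI, [1.0, 2.0], seed=19)
        b = simulate_echo_series(2, self.ROI, [1.0, 2.0], seed=19)
        np.testing.assert_array_equal(a[1].pixels, b[1].pixels)

    def test_timestamps(self):
        frames = simulate_echo_series(3, self.ROI, [1.0] * 3,
                                      frame_interval_min=10.0, seed=20)
        assert [f.timestamp_min for f in frames] == [0.0, 10.0, 20.0]
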