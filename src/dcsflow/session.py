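"""End-to-end session orchestration.

A session directory holds the pipeline inputs (curve table, accelerometer
log, optional image series manifest) and receives the outputs (flow trace,
CV tables, regression summaries, spectra, motion-independence result,
echogenicity table, and a JSON report echoing every configuration default
actually used).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from dcsflow.accelerometry import cv_accel, independence_test, read_accel, write_accel
from dcsflow.cbfi_fitting import (
    CBFiTrace,
    FitOptions,
    fit_trace,
    read_curves,
    read_trace,
    write_curves,
    write_trace,
)
from dcsflow.diffusion_model import OpticalConfig
from dcsflow.echogenicity import EllipseROI, echogenicity_ratio, load_frame
from dcsflow.spectral import average_spectra, cbfi_spectrum
from dcsflow.synthetic import (
    ScenarioConfig,
    emit_correlation_curves,
    simulate_accel,
    simulate_bfi_timeseries,
    simulate_echo_series,
)
from dcsflow.variability import fit_cv_slope, pooled_cv_regression, windowed_cv

logger = logging.getLogger(__name__)

__all__ = ["SessionConfig", "simulate_session", "run_session"]


@dataclass(frozen=True)
class SessionConfig:
    """Configuration of one analysis run.

    Defaults reproduce the measurement constants of the target protocol:
    mu_a = 0.1 cm^-1, mu_s' = 8.0 cm^-1, rho = 0.5 cm, 785 nm, 1 Hz
    acquisition, 8-s moving mean, 5-min CV windows, 0.002-0.4 Hz band.
    """

    optics: OpticalConfig = field(default_factory=OpticalConfig)
    injection_time_s: float = 300.0
    window_s: float = 300.0
    band_hz: tuple[float, float] = (0.002, 0.4)
    smoothing_s: int = 8
    subject_id: str = "subject"
    group: str = ""
    roi: EllipseROI | None = None
    seed: int = 0
    scenario: ScenarioConfig | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SessionConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: dict = {}
        if "optics" in raw:
            kwargs["optics"] = OpticalConfig(**raw["optics"])
        if "roi" in raw and raw["roi"] is not None:
            kwargs["roi"] = EllipseROI(**raw["roi"])
        if "scenario" in raw and raw["scenario"] is not None:
            sc = dict(raw["scenario"])
            sc.pop("accel_profile", None)
            if "fluct_band" in sc:
                sc["fluct_band"] = tuple(sc["fluct_band"])
            kwargs["scenario"] = ScenarioConfig(**sc)
        for key in (
            "injection_time_s", "window_s", "smoothing_s",
            "subject_id", "group", "seed",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        if "band_hz" in raw:
            kwargs["band_hz"] = tuple(raw["band_hz"])
        return cls(**kwargs)


def simulate_session(config: SessionConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate a complete synthetic session directory.

    Writes ``curves.csv`` (long format), ``accel.csv``,
    ``ground_truth.csv``, an image series with ``echo_manifest.csv``, and
    the scenario parameters; returns the paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scenario = config.scenario or ScenarioConfig(seed=config.seed)
    streams = np.random.SeedSequence(scenario.seed).spawn(4)

    t, bfi = simulate_bfi_timeseries(scenario, rng=np.random.default_rng(streams[0]))
    curves = emit_correlation_curves(
        bfi,
        config.optics,
        beta_true=scenario.beta_true,
        g2_noise_sigma=scenario.g2_noise_sigma,
        seed=np.random.default_rng(streams[1]),
        t=t,
    )
    accel = simulate_accel(
        scenario.duration_s,
        scenario.accel_profile,
        rng=np.random.default_rng(streams[2]),
    )

    paths = {
        "curves": out / "curves.csv",
        "accel": out / "accel.csv",
        "ground_truth": out / "ground_truth.csv",
        "echo_manifest": out / "echo_manifest.csv",
        "scenario": out / "scenario.yaml",
    }
    write_curves(curves, paths["curves"])
    write_accel(accel, paths["accel"])
    pd.DataFrame({"t": t, "bfi_true": bfi}).to_csv(paths["ground_truth"], index=False)

    roi = config.roi or EllipseROI(64, 64, 24, 32)
    schedule = [1.0, 1.5, 2.0, 2.8]
    frames = simulate_echo_series(
        len(schedule), roi, schedule, seed=np.random.default_rng(streams[3])
    )
    import imageio.v3 as iio

    manifest = []
    for i, frame in enumerate(frames):
        p = out / f"echo_{i:03d}.png"
        iio.imwrite(p, np.clip(frame.pixels, 0, 255).astype(np.uint8))
        manifest.append({"path": p.name, "timestamp_min": frame.timestamp_min})
    pd.DataFrame(manifest).to_csv(paths["echo_manifest"], index=False)

    scenario_dict = dataclasses.asdict(scenario)
    with open(paths["scenario"], "w") as fh:
        yaml.safe_dump(_jsonify(scenario_dict), fh)
    return paths


def run_session(
    config: SessionConfig,
    session_dir: str | Path,
    out_dir: str | Path | None = None,
    fast_fit: bool = True,
) -> dict:
    """Fit, smooth, window, regress, and report for one session directory.

    Missing inputs for a stage mark that stage failed in the report while
    independent stages still run.  Outputs are delimited text plus a JSON
    report that echoes every configuration value used.
    """
    session = Path(session_dir)
    out = Path(out_dir) if out_dir is not None else session
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "config": _jsonify(config.to_dict()),
        "stages": {},
    }

    trace: CBFiTrace | None = None
    curves_path = session / "curves.csv"
    cbfi_path = session / "cbfi.csv"
    try:
        if curves_path.exists():
            curves = read_curves(curves_path)
            trace = fit_trace(
                curves, config.optics, FitOptions(),
                smoothing_window=config.smoothing_s, fast=fast_fit,
            )
            write_trace(trace, out / "cbfi.csv")
        elif cbfi_path.exists():
            trace = read_trace(cbfi_path)
        else:
            raise FileNotFoundError(
                f"no flow input: expected {curves_path} or {cbfi_path}"
            )
        report["stages"]["fit"] = {"status": "ok", "n_points": len(trace)}
    except (ValueError, FileNotFoundError) as exc:
        report["stages"]["fit"] = {"status": "failed", "error": str(exc)}

    cv_flow = None
    if trace is not None:
        try:
            cv_flow = windowed_cv(
                trace,
                window_s=config.window_s,
                anchor_s=config.injection_time_s,
                subject_id=config.subject_id,
                group=config.group,
            )
            _write_cv(cv_flow, out / "cv_flow.csv")
            reg = fit_cv_slope(cv_flow)
            pooled = pooled_cv_regression([cv_flow])
            _write_regressions(pooled, out / "regressions.csv")
            report["stages"]["variability"] = {
                "status": "ok",
                "slope_per_min": reg.slope,
                "slope_se": reg.slope_se,
                "p_value": reg.p_value,
                "n_windows": reg.n_points,
            }
        except ValueError as exc:
            report["stages"]["variability"] = {"status": "failed", "error": str(exc)}

        try:
            spec = cbfi_spectrum(
                trace, band=config.band_hz, subject_id=config.subject_id
            )
            avg = average_spectra([spec])
            pd.DataFrame(
                {
                    "freq_hz": np.concatenate([spec.freq, avg.freq]),
                    "power_norm": np.concatenate([spec.power_norm, avg.power_norm]),
                    "subject_id": [spec.subject_id] * spec.freq.size
                    + ["average"] * avg.freq.size,
                }
            ).to_csv(out / "spectrum.csv", index=False)
            report["stages"]["spectral"] = {
                "status": "ok",
                "n_bins": int(spec.freq.size),
                "peak_freq_hz": float(spec.freq[np.argmax(spec.power_norm)]),
            }
        except ValueError as exc:
            report["stages"]["spectral"] = {"status": "failed", "error": str(exc)}

    accel_path = session / "accel.csv"
    try:
        if not accel_path.exists():
            raise FileNotFoundError(f"missing {accel_path}")
        accel = read_accel(accel_path)
        cv_motion = cv_accel(
            accel,
            window_s=config.window_s,
            anchor_s=config.injection_time_s,
            subject_id=config.subject_id,
            group=config.group,
        )
        _write_cv(cv_motion, out / "cv_accel.csv")
        stage = {"status": "ok", "n_windows": len(cv_motion)}
        if cv_flow is not None and len(cv_flow) == len(cv_motion):
            indep = independence_test(cv_flow, cv_motion)
            stage["independence"] = {
                "slope": indep.slope,
                "slope_se": indep.slope_se,
                "p_value": indep.p_value,
            }
        report["stages"]["accelerometry"] = stage
    except (ValueError, FileNotFoundError) as exc:
        report["stages"]["accelerometry"] = {"status": "failed", "error": str(exc)}

    manifest_path = session / "echo_manifest.csv"
    try:
        if manifest_path.exists():
            roi = config.roi or EllipseROI(64, 64, 24, 32)
            manifest = pd.read_csv(manifest_path)
            frames = [
                load_frame(session / row["path"], roi, row["timestamp_min"])
                for _, row in manifest.iterrows()
            ]
            reference = frames[0]
            rows = []
            for frame in frames:
                res = echogenicity_ratio(frame, reference)
                rows.append(
                    {
                        "timestamp_min": frame.timestamp_min,
                        "ratio": res.ratio,
                        "pixel_ratio_sd": res.pixel_ratio_sd,
                        "n_pixels": res.n_pixels,
                    }
                )
            pd.DataFrame(rows).to_csv(out / "echogenicity.csv", index=False)
            report["stages"]["echogenicity"] = {"status": "ok", "n_frames": len(rows)}
        else:
            report["stages"]["echogenicity"] = {"status": "skipped (no image series)"}
    except (ValueError, FileNotFoundError) as exc:
        report["stages"]["echogenicity"] = {"status": "failed", "error": str(exc)}

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def _write_cv(series, path: Path) -> None:
    pd.DataFrame(
        {
            "subject_id": series.subject_id,
            "group": series.group,
            "window_center_min": series.window_center,
            "cv": series.cv,
        }
    ).to_csv(path, index=False)


def _write_regressions(pooled, path: Path) -> None:
    rows = [
        {
            "scope": "pooled",
            "slope": pooled.pooled.slope,
            "intercept": pooled.pooled.intercept,
            "slope_se": pooled.pooled.slope_se,
            "t_stat": pooled.pooled.t_stat,
            "p_value": pooled.pooled.p_value,
            "n_points": pooled.pooled.n_points,
        }
    ]
    for subject, reg in pooled.per_subject.items():
        rows.append(
            {
                "scope": subject,
                "slope": reg.slope,
                "intercept": reg.intercept,
                "slope_se": reg.slope_se,
                "t_stat": reg.t_stat,
                "p_value": reg.p_value,
                "n_points": reg.n_points,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
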