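# dcsflow

Analysis pipeline for diffuse correlation spectroscopy (DCS) cerebral
blood-flow monitoring, built around a synthetic-data generator so every
stage is testable end to end:

- **diffusion_model** — closed-form field/intensity autocorrelations
  (g1, g2) for a semi-infinite turbid medium with Brownian scatterer
  dynamics and an extrapolated boundary.
- **cbfi_fitting** — recovery of a 1-Hz blood flow index (CBFi) trace by
  least-squares fitting of measured g2 curves (coherence factor β profiled
  out analytically; vectorized fitter for long records), followed by an
  8-s centered moving mean.
- **variability** — consecutive 5-min coefficient-of-variation windows
  anchored at the injection time, with per-subject and pooled OLS slope
  inference (two-sided t-test).
- **spectral** — normalized Welch power spectra over 0.002–0.4 Hz and
  their across-subject average.
- **accelerometry** — min-max axis scaling, 3-D motion magnitude,
  windowed CV_accel, and a flow/motion independence regression.
- **echogenicity** — elliptical-ROI mean-intensity ratios of
  ultrasound-like grayscale frames against a reference frame.
- **synthetic** — generators for all of the above: band-limited flow
  fluctuations with a post-injection variability ramp, noisy g2 curves,
  motion traces independent of flow, a viscosity-controlled Brownian
  phantom, and speckle images with a brightening ROI.
- **session / cli** — YAML-configurable end-to-end orchestration with
  delimited-text outputs and a JSON report echoing every default used.

## CLI

```sh
# generate a synthetic session (curves.csv, accel.csv, images, ground truth)
dcsflow simulate scratch/session --cv-start 0.05 --cv-end 0.20 --seed 1

# full pipeline: fit -> smooth -> CV/slope -> spectra -> motion -> echogenicity
dcsflow report scratch/session

# individual stages
dcsflow fit scratch/session/curves.csv scratch/cbfi.csv
dcsflow analyze scratch/session
dcsflow echo frame0.png frame1.png --center-row 64 --center-col 64 \
    --semi-axis-row 24 --semi-axis-col 32
```

Defaults follow the target measurement protocol: µa = 0.1 cm⁻¹,
µs′ = 8.0 cm⁻¹, ρ = 0.5 cm, 785 nm, n = 1.4, 1-Hz acquisition, 8-s moving
mean, 5-min CV windows, 0.002–0.4 Hz spectral band. Every default is
overridable by flag or YAML config (`--config`).

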