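# vethresh

Visual-electrophysiology waveform scoring and piecewise-linear
injury-threshold dose–response estimation.

The package has four parts:

- **`vethresh.synth`** — synthetic data with known ground truth: raw
  multi-sweep ERG/fVEP/flicker voltage traces built from planted components
  (a-wave, b-wave, oscillatory-potential wavelet train, PhNR, N1/P1) plus
  Gaussian noise, and dose–response tables drawn around a two-threshold
  piecewise-linear mean.
- **`vethresh.features`** — scoring of averaged traces using standard
  clinical conventions: a-wave from baseline to the first negative trough,
  b-wave from the a-trough to the highest peak, oscillatory potentials
  trough-to-peak on a 75–300 Hz band-passed copy (only wavelets before the
  b-peak; SOP is their sum), PhNR from baseline to the trough after the
  b-wave, flicker trough-to-peak per cycle, and fVEP N1→P1 amplitude and
  latency differences. Changes versus baseline are available as raw
  differences or baseline-relative ratios.
- **`vethresh.threshold`** — the dose–response model: the mean change is 0
  below both thresholds and grows linearly in the supra-threshold excess of
  rotation amplitude (Θ) and angular velocity (Φ). Candidate threshold
  pairs are postulated on a grid (defaults: 0–45° by 0.5°, 0–3500°/s by
  25°/s), each cell is fit by no-intercept least squares on the hinge
  regressors, significance comes from inverting the F distribution against
  the zero-mean null, and thresholds are selected as the lowest
  significant, adequately supported pair (within the profile-RSS confidence
  region of the best-fitting cell). Iso-probability contours, a
  supra-threshold variance-increase test, collinearity collapse for coupled
  designs, and an optional Bonferroni grid correction are included.
- **`vethresh.pipeline` / CLI** — YAML-configured end-to-end runs
  (simulate → score → model → report) with input QC and deterministic,
  seed-stamped outputs.

## CLI

```sh
vethresh full --config run.yaml --out outdir [--seed N]
vethresh simulate --config run.yaml --out outdir
vethresh analyze  --config run.yaml --out outdir
```

Example `run.yaml`:

```yaml
mode: full
seed: 1
grid: {theta_step: 0.5, phi_step: 25.0}
alphas: [0.05, 0.01, 0.001]
support_min: 3
dose_truth:
  amplitude: {theta0: 20.5, phi0: 1475.0, c1: -0.0221, sigma: 0.1}
  design: pilot          # 27-animal pilot-like design, or [[theta, phi], ...]
  timepoint: D7
```

`analyze` mode instead takes `input:` (a dose–response CSV with columns
`subject_id, eye, timepoint, theta_deg, phi_deg_s, dy_amplitude,
dy_latency`, or an XLSX workbook plus a `workbook_map:` describing its
variables-by-animals layout). Outputs per outcome/timepoint: a grid-scan
directory (`p_surface.csv`, `coefficients.csv`, `selections.json`,
`contours.csv`, contour plot) and a machine-readable `report.json`.

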