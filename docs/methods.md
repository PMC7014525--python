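# Methods

## Problem and model

The package estimates a horse's speed for every canter stride from one
inertial unit at the pommel of the saddle. The core idea is a windowing
scheme that preserves duration information: every prominent peak of the
raw dorso-ventral acceleration anchors a fixed 6 × 101-sample window
(1 s at 100 Hz), and windows are never resampled to a common cycle
length. A fast canter therefore shows more cycles per window than a
slow one, and a regression on the raw window can read speed both from
signal amplitude and from cycle count. At high speed a window can
contain more than one true stride; that is accepted by design.

Two estimators are implemented as scikit-learn style regressors:

- `OdbaRegressor` — mean overall dynamic body acceleration per window,
  linearly regressed onto speed. The ODBA pipeline is: zero-phase
  4th-order Butterworth low-pass at 10 Hz → one minimal rotation taking
  the window-mean acceleration vector onto +Z → per-axis mean
  subtraction → rectification → sum over the three axes → mean over
  the 101 samples. ODBA is non-negative and zero exactly for windows
  whose filtered, aligned acceleration is constant per axis.
- `WindowSVR` — ν-support-vector regression on the channel-major
  flattened 606-vector. Defaults: RBF kernel with γ = 1/606,
  cost C = 4, ν = 0.75 (the ϵ-tube is then chosen by the optimizer),
  per-feature standardization from training statistics.

Comparison uses 50 repetitions of a random 80/20 stride-level split; a
master seed spawns one child seed per repetition, so repetitions are
independent but reproducible. Metrics per repetition: % of test strides
with absolute error strictly above 0.6 m/s, RMSE, and Bland–Altman 95 %
limits-of-agreement width (sample SD, multiplier exactly 1.96,
differences oriented predicted − measured). Summaries are mean/min/max
of the error percentage and mean ± SD of RMSE and LoA width, and are
always recomputable from the per-repetition rows.

## Parameters that matter

| parameter | default | unit | why |
|---|---|---|---|
| window length | 101 | samples | 1 s of signal plus the anchor at 100 Hz |
| peak prominence | 1.0 | g | dorso-ventral canter peaks are several g; rejects noise ripples |
| peak separation | 0.35 | s | below the shortest plausible canter stride period |
| Butterworth cutoff / order | 10 / 4 | Hz / – | keeps locomotor band, removes high-frequency hash |
| SVR ν, C, γ | 0.75, 4, 1/606 | – | ν steers the support-vector fraction; C is the smoothness/penalty constant; γ is the common 1/n_features default |
| error threshold | 0.6 | m/s | the accuracy band practitioners consider meaningful |
| repetitions / split | 50 / 80:20 | – | damps split-to-split fluctuation |

Windows from peaks closer than 101 samples overlap and are kept by
default (one window per detected peak); a non-overlap mode that skips
peaks inside the previous window exists for sensitivity analysis.

## Design choices where the design was open

- **Gravity alignment** is per window, estimated as the window-mean
  acceleration vector of the *filtered* signal, with the unique minimal
  rotation (about the axis normal to the mean-vector/Z plane). No
  gyroscope fusion: no external attitude source is assumed. Alignment
  fails loudly when the mean magnitude is below 0.1 g (free-fall-like
  content), rather than guessing a direction.
- **Filtering is zero-phase** (forward–backward), so rectified means
  are not phase-shifted across the window.
- **ν interpretation**: the SVR's penalty constant is taken as the
  "smoothness" constant (4) and the 75 % proportion as ν of
  ν-regression, with ϵ computed by the optimizer. In ν-regression, ν
  lower-bounds the support-vector fraction and upper-bounds the
  margin-error fraction; tests assert those theoretically correct
  bounds.
- **Peak detection on raw acceleration** (no pre-filtering), with
  prominence-based detection, hence invariance to constant channel
  offsets.
- **Bland–Altman orientation** predicted − measured, so
  underestimation of fast strides appears as negative differences at
  high means.
- **Stride-level splits** by default, matching the comparison
  protocol; a horse-grouped split mode is provided because stride-level
  splitting lets strides of one horse appear on both sides — it is
  flagged, not silently changed.

## Synthetic data: what it emulates, what it does not

`simulate_canter` builds each axis from a fixed two-harmonic cycle
shape evaluated at an integrated phase, so stride frequency and
amplitude can vary continuously in time. Defaults (chosen once as
plausible canter magnitudes, configurable):

- stride frequency `f = 1.4 + 0.12·v` Hz and dorso-ventral peak
  amplitude `a = 0.5 + 0.25·v` g, affine in speed `v`;
- speeds uniform on [4, 9] m/s, spanning the competition band
  (350–400 m/min ≈ 5.8–6.7 m/s) with margin;
- white noise 0.05 g (accelerometer) and 5 deg/s (gyroscope);
- per-recording amplitude jitter (5 % SD) and frequency jitter
  (0.03 Hz SD) standing in for horse/session variability — this is what
  makes an amplitude-only ODBA read noisier than a model that can also
  count cycles, and with these defaults ODBA's rank correlation with
  true speed stays above 0.9;
- about 10 % of recordings follow the curve protocol: a commanded
  speed with a ±2 % within-curve fluctuation whose group *average* is
  broadcast to all member strides (the labelling error of averaged
  curve references is represented); commanded curve speeds are drawn
  from a slightly shrunk interval so labels stay inside the configured
  range by construction;
- reference-error injection multiplies straight-path labels by
  `1 + N(0, 0.014²)` (a reference accurate to 1.4 % of distance) and
  rescales each curve group by one shared timing perturbation.

Ground-truth peak locations are computed analytically from the phase
(the cycle shape's argmax is fixed in phase), not by running the
detector on the clean signal, so detector tests are closed-loop against
an independent truth.

The generator reproduces the *structure* that makes the method work —
speed-dependent periodicity, amplitude and window content, two
reference protocols — but it is not a biomechanically validated gait
model: no hoof-impact transients, no jump phases, no rider motion, no
sensor drift or saturation. Passing tests therefore demonstrate that
the pipeline recovers speed when the assumed signal–speed relationships
hold; they do not certify accuracy on real horses. Quantitative
published results from the original 3,221-stride, 58-horse database are
treated as directional only: the comparison here checks the *ordering*
(SVR ahead of ODBA on all three criteria), not the absolute values.

## Numerical choices and degenerate inputs

- Recording CSV is comma-separated with a `# sample_rate_hz=` comment;
  timestamps may jitter up to 10 % of the nominal period, larger gaps
  are rejected rather than resampled. Out-of-range samples (±8 g,
  ±2000 deg/s) produce validation findings but do not block processing:
  the ranges are sensor specs, not data filters.
- Round-trips (recording and stride-dataset CSV, ODBA JSON, SVR joblib
  payload with a format/version tag) preserve values to printed
  precision; version mismatches fail with both versions named.
- Degenerate fits fail loudly: fewer than 2 strides, all-identical
  ODBA values or feature vectors, non-positive speeds.
- libsvm's SMO makes SVR predictions depend on training-row order only
  through convergence tolerance; permutation invariance is asserted at
  5e-3 absolute, determinism for identical inputs is exact.
- The directional comparison and pipeline-closure checks run at 800
  synthetic strides with 50 repetitions (about a minute of CPU); metric
  oracles use 10⁵ samples for the asymptotic limits-of-agreement check.

## Known limitations

- Single-gait scope: canter only; no walk/trot discrimination or
  per-limb event detection.
- The curve protocol assumes a perfectly circular path of known radius.
- ODBA here uses acceleration only (no VeDBA variant, no dynamic
  attitude estimation).
- No hyperparameter search: defaults are documented choices, and the
  alternative regression families often used for such data are out of
  scope.
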