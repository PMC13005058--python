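# Methods

`turnsignal` implements a complete analysis pipeline for sensor-based
detection of mild cognitive impairment (MCI) from naturalistic driving:
synthetic cohort generation, stream cleaning and synchronization, turning-
maneuver extraction, multivariate time-series tensorization, deep sequence
classifiers under three fusion paradigms, participant-stratified evaluation,
and frequency-based participant risk scoring. This note documents the models,
the defaults and why they are what they are, and what the synthetic studies
do and do not demonstrate.

## The measurement model

Each driver's vehicle carries a telematics logger with three sensors: GPS
(latitude, longitude, speed in m/s at 1 Hz) and a 24 Hz accelerometer
(m/s², three body axes) and gyroscope (rad/s, three axes). Continuous streams
are segmented into trips wherever the gap between consecutive timestamps
exceeds 60 s; gaps of up to a minute are treated as part of the same trip.
Sensors fail independently, so per-participant trip counts are cross-checked
(a mismatch flags the participant), per-sensor trips are matched by timestamp
overlap, and the 24 Hz channels are merged onto the 1 Hz GPS timeline by
block averaging: every high-rate sample with timestamp in `[g, g+1)` belongs
to GPS second `g`. A blanked (NaN) sample poisons its whole block, so that
second is dropped and the trip flagged; trips missing a sensor, reduced to
fewer than 2 rows, or shorter than 30 merged rows (the size of one turn
window) are excluded with a logged reason.

## Turning maneuvers

Turns are cognitively demanding (divided attention, working memory, spatial
orientation) and are treated as candidate biomarkers. GPS coordinates are
projected to a local planar frame with the equirectangular map
`x = R·λ·cos(φ_ref)`, `y = R·φ` (R = 6371 km, φ_ref = per-trip mean
latitude); at city scale this is conformal enough that heading geometry is
preserved. The detector thresholds the magnitude of the heading change
between successive path steps at 10° (0.174533 rad). Two operationalizations
are provided: the default computes step headings by `atan2(dy, dx)`, which is
defined everywhere; the alternative `slope` mode thresholds the arctangent of
dy/dx and discards samples adjacent to dx = 0 steps, reproducing the
undefined-gradient filter that slope-based detection requires. Candidates at
zero speed (stationary jitter, not maneuvers) are discarded. Runs of
candidates spaced ≤ 2 samples apart are one maneuver and collapse to their
median index (lower median for even runs — a deterministic tie-break). A
±15 s window around each peak yields a 31-row, 10-channel segment;
edge-truncated windows are linearly interpolated back to 31 rows with exact
endpoints.

The 2-sample adjacency gap merges detection jitter within one maneuver
without bridging distinct turns; it is the smallest gap that absorbed
double-peaks on the synthetic routes. Detector quality is quantified against
an independent brute-force reference — an exhaustive scan of successive
heading differences over the generated path — and exceeds 0.9 precision and
recall over hundreds of seeded trips (see `validation.detector_agreement`).

## Channels and features

The model input is a fixed 10-channel set: speed, the three linear
accelerations, the three angular velocities, and three derived angular
accelerations — temporal gradients of the gyroscope channels (central
differences on interior points, one-sided at the ends, dt = 1 s on the merged
grid). Rapid within-turn fluctuation of these channels is the behavioral
signature of interest: micro-corrections in steering and speed control.
Derivatives are taken after synchronization because the tensors consume the
1 Hz grid; deriving at 24 Hz and block-averaging afterwards is nearly
identical for these smooth signals and is not the default.

The static baseline summarizes a trip by the mean and population SD
(ddof = 0, fixed for reproducibility) of the seven raw channels — 14 features
feeding a random-forest benchmark, the representation classical telematics
studies use.

## Tensors

Variable-length sequences are resampled by per-channel linear interpolation
over normalized time (monotone-safe, endpoint-exact; richer kinds are
configurable but unnecessary at these smoothness levels). Four views exist:

- **trip**: N × 10 × 1200. L₁ = 1200 spans the bulk of trip lengths without
  excessive compression.
- **turn**: per-turn windows (N_turns × 10 × 31) or per-trip concatenation of
  windows in temporal order. Concatenation is the default granularity for
  turn-only modelling.
- **early fusion**: the turn concatenation is resampled to L₁ and stacked
  with the trip view along the channel axis → N × 20 × 1200.
- **late-fusion pair**: the trip view plus the turn concatenation at its own
  length L₂ = 310 (ten native-resolution windows — keeps the turn branch at
  native resolution while bounding its length; configurable).

Zero-turn trips would break row alignment across views; the default policy
zero-pads their turn block and records a mask (the `exclude` alternative
drops them from fusion experiments).

## Classifiers

The model zoo is implemented on a small reverse-mode automatic-
differentiation engine (`turnsignal.nn.autograd`, numpy float32) providing
broadcast arithmetic, matmul, strided/dilated 1-D convolution, the usual
nonlinearities, reductions and a fused weighted softmax cross-entropy.
Architectures are compact instantiations of the standard time-series-
classification families:

- **1D-CNN / TinyFCN / Inception variants / ResNet-TSC**: TinyFCN is the
  classic fully-convolutional network — three conv-BN-ReLU blocks (32/64/32
  filters, kernels 8/5/3) with global average pooling; Inception variants use
  2–3 reduced multi-kernel blocks (kernels 3/5/9, optional bottleneck and
  residuals); ResNet-TSC stacks three residual triple-conv blocks.
- **GRU / LSTM**: single layer, hidden 64, classified from the final hidden
  state or an additive-attention pooling over time (multi-head = 4
  independent heads, concatenated).
- **TCN / TinyTCN**: four dilated causal conv levels (dilations 1/2/4/8,
  widths 32/16) with residual links; optional scaled-dot-product
  self-attention pooling.
- **Dual encoders (late fusion)**: two weight-independent encoders of the
  same family consume the trip and turn branches; latents merge by
  concatenation or a learned gate `g = σ(W[z_trip; z_turn])`,
  `z = g·z_trip + (1−g)·z_turn` — the simplest learned convex combination.

Training uses AdamW (lr 1e-3, decoupled weight decay 1e-4), cosine-annealed
learning rate with `T_max` equal to the epoch count, weighted cross-entropy
(`w_c = n/(2 n_c)`) when class weighting is on, batch size 32, 200 epochs at
full scale. One integer seed drives initialization, batch order and dropout.

## Evaluation protocol

Folds are split at the **participant** level: within-class seeded shuffle,
then round-robin assignment into k = 7 folds, so each test fold's class ratio
matches the cohort within rounding and no driver contributes to both sides of
a fold (asserted in the code, not assumed). Channel scaling, when enabled, is
fit on training-fold data only (zero-variance channels fall back to a unit
divisor with a warning). Metrics are accuracy, balanced accuracy (mean of
per-class recalls), ROC AUC on pooled test-trip probabilities (recorded as
missing when a fold's test trips are single-class and excluded from the AUC
mean), precision, recall and F1, averaged unweighted across folds. The
decision threshold is 0.5 on the positive-class probability, configurable.

## Risk scoring

MCI is episodic: an affected driver may look impaired on a minority of trips.
Trip-level predictions are therefore aggregated into a per-participant
**risk score** — the proportion of trips classified impaired, in [0, 1] —
which clinicians threshold to taste: 10% prioritizes sensitivity for
screening, 50% precision for specialist settings. Hard per-trip labels are
the default (a probability-mean variant sits behind a flag). Majority vote
(impaired iff risk > 0.5, with exact ties breaking to impaired —
sensitivity-first, and what makes the vote identical to a 0.5 threshold) is
retained as the baseline it replaces.

## The synthetic cohort

Real cohorts of clinically characterized drivers are private, so the
generator emulates the statistical structure the analysis assumes. Routes
are 2-D waypoint polylines: straight constant-speed segments joined by
60–120° corners traversed at a constant yaw rate over 4 s (well above the
10°/s detection threshold), with slow speed drift, corner slow-downs and
Gaussian jitter. GPS positions integrate the jittered kinematics and are
mapped to latitude/longitude around a Phoenix-area reference; IMU channels
upsample the 1 Hz kinematics to 24 Hz and add sensor noise. Trips are
separated by > 60 s gaps; malfunctions (per-sensor missing trips, mid-trip
cutoffs, blanked value blocks) are injected per configured probabilities.

The impairment signature multiplies the SD of within-turn speed and yaw-rate
fluctuation by `effect_size`; each MCI trip expresses it with probability
`impaired_trip_fraction` (a per-trip Bernoulli gate modelling day-to-day
variability). `effect_size = 1` reproduces the null exactly — the classes are
exchangeable by construction. Baseline fluctuation SDs (0.4 m/s speed,
0.04 rad/s yaw, with matching high-frequency IMU noise) sit at roughly 10% of
typical corner yaw rates: large enough that the inflated fluctuation is a
salient, recoverable component of the signal rather than being swamped by
corner-to-corner geometry variation, small enough that individual trips
remain realistic. The default cohort mirrors the analyzed-study structure:
12 healthy + 7 MCI drivers with a wide spread (3–46) of trips each.

What the generator does **not** emulate: road networks and traffic, realistic
route topology, vehicle dynamics beyond kinematic jitter, age/sex effects,
GPS multipath outliers, clock drift. Passing recovery tests therefore shows
that the pipeline extracts a within-turn-fluctuation effect of the stated
size under clean conditions — not that real MCI produces such an effect.

## Demonstration problem sizes

The effect-recovery and null-calibration studies run on a scaled-down
version of the default cohort, chosen as the package's standard demonstration
conditions (`validation.DEMO_COHORT` / `DEMO_TRAIN`): 19 drivers with 3–5
trips of 120–240 s and 4–8 turns each (≈ 75 trips; turn-dense trips carry the
signature clearly), and a shortened schedule — 20 epochs at
batch size 8 with lr 3e-3 and per-channel normalization — whose optimizer
step count at this cohort size approximates what the full-scale configuration
(200 epochs, batch 32) delivers on a hundreds-of-trips cohort. Under these
conditions the TinyFCN reference model's cross-validated trip-mode AUC
exceeds 0.8 (median over 5 seeds) at effect size 2.5 with every MCI trip
impaired, and stays within [0.4, 0.6] at effect size 1. The sporadic-
impairment demonstration uses a stylized trip classifier (90% sensitivity,
5% false-positive rate) to isolate the aggregation layer: with 30% of MCI
trips impaired, the 10% risk threshold detects strictly more true MCI drivers
than majority voting across 10 seeded cohorts.

## Numerical choices and degenerate inputs

- Interpolation requires ≥ 2 samples; single-row trips are excluded upstream.
- Empty tensor inputs produce shape-(0, C, L) tensors rather than errors.
- Batch-norm running statistics use momentum 0.1; evaluation mode is
  deterministic.
- AUC is undefined on single-class folds and recorded as missing.
- The detector returns no peaks for paths shorter than 3 samples.
- All randomness flows from integer seeds; repeated runs are bit-identical
  on one CPU.

## Known limitations

- Recurrent models are slow at trip length 1200 on CPU (the engine loops over
  time steps in Python); convolutional families are the practical default at
  full length.
- The reference architectures are compact conventions, not tuned
  reconstructions; absolute metric levels on real data would differ.
- Trips whose sensors disagree on segmentation are matched by timestamp
  overlap; pathological overlap patterns (one long sensor trip spanning two
  GPS trips) resolve to the larger overlap rather than being split.
- The risk score weighs every trip equally; drivers with very few trips have
  high-variance scores (a single misclassified trip moves a 3-trip driver by
  0.33), which is inherent to frequency-based scoring.
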