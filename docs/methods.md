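# Methods

This note documents the models, conventions and numerical choices behind
`pafnet`, and what the synthetic-data experiments do and do not establish.

## Problem and model

The task is binary classification of fixed-length windows of consecutive
R-R intervals (beat-to-beat times, seconds): windows from PAF subjects
recorded at least 45 minutes before any AF episode (class PAFN) versus
windows from normal-sinus-rhythm subjects (class N). A classifier that
separates these classes acts as an onset predictor with at least a
45-minute horizon, and because the window slides one beat at a time it
re-scores the patient at every heartbeat.

The classifier is a 26-layer 1D CNN (counted as in its layer table: input
layer, five conv/batch-norm/ReLU blocks with 16/32/64/128/256 feature maps
— the last four followed by length-2 max pooling — flatten, a 512-unit
dense/batch-norm/ReLU/dropout block, and a single sigmoid output unit).
Convolutions use 'same' padding and stride 1; pooling alone downsamples.
Input size N only changes the flatten length and hence the first dense
layer.

### Architecture calibration

Published descriptions of this architecture leave four accounting details
ambiguous (and the prose and the layer table contradict each other on
kernel size, dense width and dropout; the layer table is taken as
authoritative since only it yields 26 layers with 5 convolutions).
`calibrate_architecture` closes the remaining gaps empirically: it
enumerates the 16 combinations of

* first-convolution kernel length ∈ {1, 8},
* convolution bias on/off,
* batch-norm parameters per feature ∈ {2, 4} (scale/shift only, or
  including the running mean/variance as non-trainable parameters),
* pooling output-length rounding ∈ {floor, ceil},

and keeps the unique variant whose closed-form totals match the three
published parameter counts (878,017 / 1,271,233 / 2,057,665 at N = 50,
100, 200) simultaneously: first kernel 1, bias on, 4 batch-norm parameters
per feature, ceil pooling. The search is bounded, exact, and re-run (or
cached) at build time; a deliberately perturbed variant misses at least one
total, which the tests use as a negative control.

A consequence of ceil pooling worth noting: the parameter total is
non-decreasing but not strictly increasing in N — nearby input sizes can
ceil-halve to the same flatten length (50 and 64 both leave 4 taps), giving
identical totals.

## Signal processing conventions

* **Band-pass 0.1–100 Hz** — 4th-order Butterworth applied
  forward-backward (zero phase), because any phase distortion would shift
  R-peak positions, which are the quantity of interest. If 100 Hz does not
  fit under Nyquist the upper cutoff is clamped to 0.95·Nyquist and logged.
* **Baseline removal** — subtraction of a running median with window
  round(0.85·fs) forced odd (reflect padding). The median estimates the
  baseline because the QRS occupies a small fraction of the window.
* **Low-pass** — 4th-order Butterworth, zero phase. The cutoff is not
  pinned by the source material; the default is 40 Hz, comfortably above
  the QRS band, and configurable.
* The chain is linear and length-preserving but only approximately
  idempotent: a second pass changes the output by 5–8% RMS on synthetic
  ECG, because the 30 ms QRS template carries real energy in the 40 Hz
  low-pass transition band which every pass attenuates further. Exact
  idempotency would require a brickwall filter.
* **R-peak detection** — the classical threshold-on-difference scheme:
  first difference → squaring → 150 ms moving-window integration →
  candidate peaks at least 200 ms apart → adaptive acceptance threshold of
  0.3× an exponentially updated running peak estimate (update weight
  0.125) → refinement to the local maximum of the filtered signal. The
  threshold is relative to the signal's own level, so detection is
  invariant to global amplitude scaling. Accuracy is contracted against
  synthetic ground truth: on clean synthetic ECG all peaks within ±10 ms;
  at white noise of 10% of the R amplitude, ≥99% within ±20 ms with ≤1%
  spurious.
* **Intervals** are carried in seconds (not samples), which normalizes
  records digitised at different rates. `clean_rr` (bounds 0.3–2.5 s) is
  available but off by default: whether implausible intervals were
  post-filtered in the reference workflow is unknown, so the default
  pipeline does not.

## Record selection and labeling

PAFN content is extracted from rhythm-annotated records under the
protocol: AF episodes of ≥5 minutes qualify and carry a 45-minute guard
zone on both sides that is excluded from PAFN content; AF spans shorter
than 5 minutes do not trigger the guard zone but their own span is still
excluded; atrial-flutter and junctional-rhythm spans are excluded
outright. Eligible time is cut into non-overlapping 30-minute slices.
The interaction of sub-5-minute AF with the distance rule is not fully
specified by the protocol's wording; the choice above (exclude content,
no guard) is exposed as a policy flag (`guard_short_episodes`). Windows
carry `time_to_onset` (gap from the window's last beat to the next
qualifying onset) so that accuracy can be profiled by time before onset
(default 5-minute bins over 45–75 minutes; bin width configurable, and
empty bins report missing rather than zero).

## Training

* Stratified k-fold (default 10): within each class, indices are shuffled
  under the seed and dealt into k near-equal chunks, guaranteeing every
  block's class ratio within one percentage point of the global ratio and
  exact reproducibility of the split under the seed.
* Loss binary cross-entropy; optimizer Adam (lr 1e-3, β = 0.9/0.999);
  epochs 9; batch 512; classification threshold 0.5. Loss and optimizer
  are the standard pairing for a sigmoid output; the remaining values
  follow the reference training setup.
* Per-fold metrics (Sen/Spe/Acc, exact rational arithmetic from confusion
  counts) are computed from each fold's own model on its held-out tenth —
  the only reading consistent with disjoint validation sets. Summary
  statistics are the arithmetic mean and the *sample* variance (divisor
  n−1) on the fractional scale; this is the convention that reproduces the
  reference table's printed variances from its own per-fold rows.
* At test time the k fold models form an ensemble by averaging sigmoid
  outputs.

## The numpy network engine

No deep-learning framework is part of the dependency set; `pafnet.nn` is a
small, fully tested engine implementing exactly the layer vocabulary the
architecture needs. Numerical choices:

* float32 parameters and activations (float64 available for gradient
  checking; the test suite verifies analytic gradients against finite
  differences through the full stack, including batch-norm batch
  statistics and ceil pooling).
* Convolutions are evaluated as im2col + BLAS matrix products; 'same'
  padding for even kernels pads one sample less on the left.
* Batch normalization: eps 1e-3; running statistics are bias-corrected
  exponential moving averages (momentum 0.9, debiased by 1−m^t, the same
  correction Adam applies to its moments). Plain EMAs from a 0/1
  initialization leave inference statistics far from the batch statistics
  after the few dozen updates a small training run performs, which
  silently destroys held-out accuracy while training accuracy is perfect.
* Max pooling uses ceil rounding (odd tails survive as their own pool),
  matching the calibrated accounting variant; ties in a pool resolve to
  the first index.
* Dropout is inverted (scaling at train time), rate 0.25.
* Binary cross-entropy clips probabilities to [1e-7, 1−1e-7]; training
  aborts with a diagnostic on non-finite loss.

Weight initialization is Glorot-uniform under the classifier's
`random_state`; fold f trains under seed `seed + f`. Fold assignment,
initialization, epoch shuffling and dropout masks are all deterministic
under the configured seed. (Exact weight trajectories are deterministic
here because the engine is single-threaded numpy; only split determinism
is contractual.)

## Synthetic data: what it emulates, and what it does not

`generate_rr` emulates two regimes around a 0.8 s mean interval
(75 bpm): **NSR** with Gaussian beat-to-beat jitter (SD 0.04 s) plus a
3% sinusoidal modulation with a 4-beat period standing in for respiratory
sinus arrhythmia; **PAF_PRONE** with doubled jitter (SD 0.08 s) and, with
probability 0.05 per beat, a premature couplet — a short interval of
0.65× the local mean followed by a compensatory pause of 1.35× the local
mean. All intervals clip to 0.3–2.5 s. These defaults are physiologically
plausible and make the classes statistically separable (larger variance
plus couplet signatures), which is the property the pipeline tests need.

`generate_ecg` renders an R-R sequence by placing a 30 ms raised-cosine
deflection at each cumulative R-time, with optional sinusoidal baseline
wander (0.25 Hz) and white noise, returning exact ground-truth peak
indices. It deliberately omits P and T waves, fibrillatory waves, ectopic
morphology and non-stationary noise.

Consequently, passing tests establish that the pipeline's mechanics are
correct (detection against known truth, window bookkeeping, training and
ensembling, streaming equivalence) and that the network can learn a
variance/ectopy-based separation. They do not establish clinical
performance: real pre-AF dynamics are subtler than the synthetic contrast,
and real ECG noise is harsher than white noise on a clean template. The
reference databases (AFPDB/AFDB/NSRDB) remain necessary for paper-scale
figures.

## Problem sizes used by the test suite

The bundled experiments run at desk scale as the package's own choice of
test conditions: the cross-validated learnability check uses 1,000 windows
per class at N = 100 (two 599-interval records per class, step-1 windows),
ten folds, 9 epochs, batch 512 — together with a label-shuffling control
that must sit at chance. Streaming/batch equivalence uses a 2,000-beat
record (1,901 per-beat predictions, tolerance 1e-6). R-peak recovery uses
a 600-beat record at 250 Hz. The architecture accounting is exact at the
full published sizes (it costs only arithmetic).

## Known limitations

* Signal formats: only format-16 waveform-database records and text
  annotation files; no EDF, no binary `.atr` (annotations use the
  rdann-style text form).
* The detector is not tuned for pathological morphologies (bundle-branch
  block, pacemaker spikes) and performs no beat-type classification.
* Per-beat latency is measured and reported by `replay` but never asserted:
  it is hardware-dependent.
* The CNN engine is CPU/numpy; it is adequate for the bundled problem
  sizes, not for training on the full 113k-window database scale at
  interactive speed.
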