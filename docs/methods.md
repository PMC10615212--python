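# Methods

`gaitkit` implements a complete gait-event detection pipeline for bilateral
foot-worn inertial sensors, together with the synthetic data, reference
standard, walking-bout rules, and agreement statistics needed to train and
evaluate it end to end. This note documents the models, the defaults and why
they are what they are, the numerical choices, and the limits of what the
synthetic experiments can show.

## Problem and model

Clinical gait analysis segments walking into gait cycles bounded by gait
events: the initial contact (IC), when the foot first touches the ground, and
the final contact (FC), when it leaves it. From per-side IC/FC sequences the
temporal gait parameters follow directly — stance time = FC − preceding IC,
swing time = next IC − FC, stride time = IC-to-next-same-side-IC, with
stance + swing = stride as an exact identity.

The detector is a temporal convolutional network (TCN) mapping the raw
12-channel signal (3-axis accelerometer + 3-axis gyroscope per foot, 100 Hz,
both feet on one clock) to a per-timestep probability distribution over five
classes: no event, IC left, FC left, IC right, FC right. Because the network
learns event-locked signatures from data, it needs no sensor-to-segment
alignment and no hand-tuned axis heuristics — the property that matters for
unsupervised wear by patients.

### Architecture

Six residual blocks; block *m* uses dilation 2^(m−1) (1…32). Each block is
two sequences of [dilated convolution (64 filters, kernel 3) → batch
normalization → ReLU → dropout], plus a residual path that is the identity,
or a kernel-1 convolution where channel counts differ (block 1: 12 → 64);
branch outputs are summed and passed through a final ReLU. A per-timestep
dense layer and softmax produce the class probabilities. The receptive field
is 1 + Σ_m 2·(kernel−1)·2^(m−1) = 253 samples (2.53 s at 100 Hz), verified
empirically by a perturbation probe in the tests.

Convolutions are non-causal and zero-padded to preserve length: the intended
use is offline analysis of recorded bouts, where a centered window halves the
event-to-context distance relative to a causal stack. The implementation is
pure NumPy — dilated convolutions as sums of per-tap matrix products,
hand-written backpropagation, and Adam — which keeps the package free of any
deep-learning framework dependency and makes training bit-reproducible given
the seed (single-threaded BLAS caveats aside).

### Supervision and training

Point events are untrainable as one-hot targets, so targets are triangular
kernels: value 1 at the event sample, decaying linearly to 0 at ±0.10 s
(radius below the ±0.25 s matching tolerance, so label smoothing cannot turn
a miss into a hit). The null class takes the leftover mass; rows are
rescaled in the rare case overlapping kernels exceed 1, so every row is a
distribution. Same-class events closer than the radius trigger a warning and
take the pointwise maximum.

The loss is per-timestep cross-entropy with inverse-frequency class weights
(configurable; the null class outweighs event classes roughly 20:1, and
unweighted training pushes event probabilities below the 0.5 detection
threshold for much longer). Inputs are standardized per channel with
training-set statistics stored in the model checkpoint. Optimization is Adam
(learning rate 1e-3) on 10 s windows (1000 samples ≥ receptive field), batch
size 8, at most 30 epochs with early stopping on validation loss (patience 8)
and restoration of the best parameters. None of these optimizer settings is
part of the published architecture; they are this package's choices, made
once to obtain stable convergence on the synthetic data.

Splits are by subject — never windows of one subject in two sets — with
floor-based allocation of 20% validation and 20% test per stratum and the
remainder (≈60%) for training.

### Event extraction

Local maxima of each event-class probability with height ≥ Δ_Pr = 0.5 become
events; maxima of the *same* class closer than Δ_t = 0.5 s are pruned keeping
the higher (earlier on ties; a plateau's first sample is its peak; boundary
samples qualify if they dominate their one-sided neighborhood). The distance
constraint is deliberately per class: an IC follows the contralateral FC by
roughly a swing time (~0.4 s), so a cross-class constraint would delete valid
events. Long recordings are processed in overlapping windows (overlap =
receptive field) and only each window's central region is kept, removing
padding-boundary artifacts; output length always equals input length.

## Reference standard and walking bouts

Pressure-insole reference: foot-ground contact holds while at least three
sensing elements *of the same spatial neighborhood* are simultaneously
active. The package reads "same neighborhood" as a connected component of
the element adjacency graph (default: 16 elements on a 4×4 grid with
4-adjacency). Mutual pairwise adjacency would be unsatisfiable — a grid
graph has no triangles — while connectivity matches the intent that isolated
spurious elements never constitute contact. Contact runs shorter than 30 ms
are discarded as bounce (configurable debounce). Each maximal run emits IC at
its first and FC at its last sample.

Insole events are fused with an external IMU-based reference stream by
one-to-one greedy pairing within 0.25 s per (side, kind); paired events keep
the insole timing (insole priority), unpaired events pass through. The
IMU-only reference detector itself is out of scope; the pipeline accepts its
events as a CSV stream, and the synthetic experiments stand one in by
jittering the ground truth (σ = 20 ms).

Bout rules: strides are consecutive same-side IC pairs (FC attached when
exactly one falls strictly between); valid strides last 0.2–3 s (bounds
inclusive — the published wording is ambiguous, inclusivity is configurable)
and, when a length is supplied externally, measure ≥ 0.15 m (the filter is
skipped when lengths are absent, since trajectory reconstruction is out of
scope). Strides pool across sides in time order; a gap > 3 s between one
stride's end and the next stride's start splits bouts (a rest of exactly 3 s
is contained). A bout needs ≥ 2 left and ≥ 2 right valid strides; analysis
keeps bouts ≥ 10 s.

## Evaluation

Reference and predicted events match one-to-one per (side, kind) when
|t_ref − t_pred| ≤ 0.25 s (inclusive), greedily by ascending absolute error.
Greedy matching provably equals the exhaustive optimal assignment whenever
each stream's internal spacing exceeds twice the tolerance — guaranteed here
because the detector enforces a 0.5 s minimum interpeak distance — and the
brute-force oracle test draws its instances from that family. On adversarial
instances with sub-tolerance spacing, greedy can differ from the
maximum-cardinality optimum; such streams cannot be produced by this
detector.

Scores: recall = TP/(TP+FN), precision = TP/(TP+FP), F1 harmonic mean; zero
denominators yield NaN, never a silent 0. Time errors use ε = t_ref − t_pred
(positive = early detection), summarized by median and IQR (linear
interpolation quantiles, Q3 − Q1). Temporal parameters are computed per
system only for strides whose two ICs and intervening FC are all present,
paired by side and IC time. Agreement per parameter: bias = mean(predicted −
reference), limits of agreement = bias ± 1.96·SD (sample SD; the multiplier
is configurable since some conventions plot ±1 SD), per-stride (average,
difference) pairs exported for Bland–Altman plots. Relative errors are
normalized per stride (mean of |d_i|/ref_i, in percent). Internals keep full
precision; integer-percent and 10-ms rounding happen only in the report
layer.

## Synthetic data

The simulator emulates a multi-subject free-living study at the level the
detector cares about: quasi-periodic bilateral stride sequences (stride time
= 1/cadence with per-stride Gaussian variation; stance fraction Gaussian,
resampled into (0.05, 0.95)), a ~50% contralateral phase offset, rests of
4–8 s between bouts (> 3 s, so bout segmentation is exercised), an arbitrary
random sensor orientation per foot, and white sensor noise (0.3 m/s²,
3 deg/s). Signals are a minimal physically-motivated template — gravity,
a damped 18 Hz impact transient at each IC, a positive mid-swing
angular-velocity lobe between FC and next IC with short negative lobes at
the events — because the detector must only learn event-locked signatures.
Ground-truth event times are snapped to the 100 Hz grid, which keeps
stance + swing = stride exact and makes the zero-jitter insole round-trip
(simulate → contacts → events) recover the truth bit-exactly.

Insole activations span each stance interval with independent Gaussian
per-element jitter (default 5 ms, truncated so activation precedes
deactivation) and per-stance element dropout (default 2%). Note that the
*derived* contact onset under the ≥3-element rule is a low order statistic
of the per-element jitters and therefore sits slightly early by construction
(≈ −1 σ_jitter); per-element onsets themselves are unbiased, which is what
the tests assert.

Study-scale defaults: 30 subjects, 2 bouts of 12–16 strides each (~40 s gait
per subject, ~20 min total), cadence means drawn per subject from 0.70–0.85
strides/s (stride times 1.18–1.43 s) and stance fractions from 0.66–0.73,
spanning the range reported for healthy through slow pathological gait.
These sizes keep the complete train-and-evaluate experiment within a few
minutes on one CPU core while leaving enough test strides (~300 per kind)
for stable percentages.

What passing synthetic tests do *not* show: robustness to real pathological
variability (festination, shuffling, freezing), turning and stairs, soft
tissue and footwear artifacts, sensor drift, or imperfect bout
pre-extraction. The simulator's pathology knobs (slower cadence, higher
stance fraction, higher variability) change timing statistics, not
waveform morphology; claims about real cohorts require real data.

## Known limitations

- The TCN is CPU-bound NumPy; it is deliberately small-scale and has no GPU
  path. Training beyond desk scale would want a framework backend.
- One joint 5-way softmax head is implemented; a per-side two-head variant
  (two 3-way softmaxes) is a conceivable alternative that was not built.
- The published architecture's grid search is not reproduced; the defaults
  are the final published architecture.
- Quantile conventions differ across software; this package uses
  linear-interpolation quantiles throughout and documents IQR = Q3 − Q1.
- Table-level worked examples use published per-cohort counts as inputs; one
  printed percentage (COPD FC recall) is internally inconsistent with its own
  row's counts (98.37% → 98, printed 99) and the counts are taken as
  authoritative.
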