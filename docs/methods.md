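# Methods

This note records the models, conventions and design choices behind
`liftrisk`, in the spirit of a model-documentation page: what is computed,
under which assumptions, and where the genuinely open choices were made.

## Problem and data model

One lifting trial is an F × 36 signal block: 6 IMU placements (upper back
T12, left wrist, right wrist, dominant upper arm, waist, dominant thigh) ×
{accelerometer, gyroscope} × {x, y, z}, sampled at 25 Hz, F ≤ 750 frames
(30 s ceiling; typical lifts last 10–15 s). Column order is fixed and
placement-major: channel index = placement·6 + sensor·3 + axis. Each trial
carries an ACGIH zone 1–12; zones collapse to risk classes

    low {4, 5}   medium {6, 7, 8, 9}   high {1, 2, 3, 10, 11, 12}

so balanced zones give a 1:2:3 class imbalance (e.g. 120/240/360 of 720).

## Synthetic trial generator

The simulator emulates the *statistical* structure the classifier relies
on, not lifting biomechanics. A trial is baseline Gaussian noise
(`noise_sd`, default 0.25 signal units) plus two Gaussian-windowed
oscillatory bursts — object pickup at 12% of the trial and the return to
upright at 88% — with envelope width σ = 0.4 s and carriers at 5 Hz
(accelerometer) and 4 Hz (gyroscope), both inside the 2–12 Hz analysis
band. Burst amplitude per placement is

    weight_p · (1 + class_index · class_separation · sensitivity_p)

with weights (1.0, 0.85, 0.85, 0.5, 0.4, 0.3) and class sensitivity
(1.0, 1.0, 1.0, 0.3, 0.2, 0.1) over (back, wrists, arm, waist, thigh): the
class signature lives mainly on the back and wrist channels, so the
discriminative information is the loading *pattern* across placements.
Durations are uniform on `duration_range` (default 10–15 s); phases are
random per channel and burst. The full design (10 subjects × 12 zones × 6
trials) reproduces the 720-trial benchmark geometry.

What the generator does **not** emulate: subject-specific movement styles
(subject id only partitions the seed stream), gravity components and sensor
drift (the band-pass removes both anyway), zone differences *within* a risk
class, variable burst timing beyond duration scaling, and any kinematic
coupling between channels. Consequently, passing tests show the pipeline
can recover class-dependent burst/loading structure through the full
encode-train-evaluate path — they say nothing about accuracy on real
lifting data.

With `class_separation = 0` the classes are exchangeable by construction;
with `noise_sd = 0` and large separation a nearest-centroid rule on channel
energies is already perfect. Both extremes are asserted in the tests.

## Preprocessing

Pipeline order is fixed: **filter → pad → scale → encode**.

* Filter: order-2 Butterworth band-pass, 2–12 Hz at 25 Hz sampling,
  realised as second-order sections (stable with the upper edge at 12 of
  12.5 Hz Nyquist) and applied forward–backward. Zero-phase filtering was
  chosen because trials are processed offline and group delay would shift
  burst positions; a causal single-pass mode is available for
  streaming-style use. Note the effective magnitude response is the square
  of the single-pass response.
* Padding: trials are rearranged to 12 × F × 3 and zero-extended to 750
  frames; trials longer than the window are refused rather than silently
  truncated.
* Scaling: per axis-channel (36 channels) affine transform fitted on the
  training fold only — z-score by default, min–max to [−1, 1] as an option.
  Padding cells are reset to exactly 0 *after* scaling, which is the
  neutral value under z-scoring. Fitted parameters are immutable; held-out
  data may legitimately exceed the min–max bounds.
* Encoding: per axis, the 12 × 750 slice is flattened time-major (stream
  varies fastest, sequence index i = stream + 12·frame) and wrapped
  row-major into 95 × 95; the final 25 cells per channel are padding.
  This wrapping maximises time locality within image rows. The encoding is
  a position bijection, which is why scaling before encoding is exactly
  equivalent to scaling after it; it is done on the tensor side, where
  "per channel" is directly expressible.

The 36 × 750 reading of the signal block (treating each axis as its own
row) appears in informal descriptions of this encoding, but only the
12 × 750 × 3 layout makes the 95 × 95 × 3 arithmetic work
(12 · 750 = 9,000 ≤ 95² = 9,025); the package implements the latter
throughout, with "channel" for scaling purposes meaning each of the 36
stream-axis combinations.

## Cross-validation

"Per-zone stratified Monte-Carlo CV": four *independent* random splits in
which every zone individually contributes 75% of its trials to training
and 25% to testing. Independent draws (rather than a disjoint 4-fold
partition) are the only reading under which four folds can each hold 25%
of every zone; they also guarantee no zone is ever absent from either
side. Per-zone test quotas use floor-plus-largest-remainder so the global
test fraction is hit exactly when possible, and every zone keeps at least
one trial on each side. Splits are by trial; subject-wise splitting is
deliberately not the default (the benchmark protocol randomises trials).

## Models and training

Five architectures share one training protocol (Adam with β₁ = 0.9,
β₂ = 0.999; categorical cross-entropy; L2 with λ = 10⁻⁵ on the final
softmax dense layer only; early stopping). The proposed model is the
average-pooling VGG-B variant described in the README; the max-pooling
variant differs *only* in the pooling operator (asserted structurally in
the tests). Convolutions are size-preserving ("same" padding, VGG
convention), so pooling alone downsamples: 95 → 47 → 23 → 11, flatten
11·11·128 = 15,488, and the full model has 16,143,619 trainable
parameters.

Open choices, resolved as follows:

* The 1024-unit dense layer's activation is unstated in the architecture
  description (only the conv layers are explicitly ReLU); it gets ReLU —
  a linear hidden layer would collapse with the softmax layer into a
  single affine map.
* Batch size 32 and an epoch ceiling of 500 are defaults, not protocol;
  scaled-down runs in the tests use batch 8 and 16 epochs.
* Early stopping monitors the **training** loss (patience 10, min-delta 0,
  best-loss weights restored). There is no inner validation split; this
  differs from common practice and is deliberate — the protocol tunes
  hyperparameters on cross-validated results only, and per-epoch training
  loss is the monitored curve.
* The sequence model (DeepConvLSTM family) unrolls the 12 × 750 × 3 tensor
  into 750 steps of 36 features, applies four stride-2 1-D convolutions
  (64 filters, kernel 5; 750 → 375 → 188 → 94 → 47 steps) and two LSTM
  layers (128 units), softmax on the final hidden state. The stride is a
  departure from the cited architecture's unit stride: across 750 steps —
  most of them zero padding — LSTM gradients vanish and the model cannot
  learn; compressing time before recurrence fixes this while keeping the
  column-sliding feature extraction. All counts are configurable.
* The pooling-free "simple CNN" is three size-preserving conv blocks
  (32/64/128 @ 3×3, ReLU) + flatten + softmax; the MLP is flatten →
  dense 1024 ReLU → dropout → softmax.
* Prediction ties break toward the higher risk class — conservative for a
  safety application.
* Training aborts with a diagnostic on a non-finite loss (the unstable
  learning-rate regime); the tests exhibit α = 10⁻² terminating at higher
  loss than α = 10⁻³ on a memorisation task in the majority of seeded
  repeats.

The engine (`liftrisk.nn`) is a small CPU library: im2col + GEMM
convolutions, float32 by default (float64 for gradient checking), explicit
backward passes verified against central finite differences layer by
layer. Dropout is inverted (identity at inference); batch-norm uses batch
statistics in training and running averages at inference, so prediction is
deterministic for fixed weights. Training is bit-reproducible given the
seed on a fixed software stack.

## Metrics

Confusion matrices are actual × predicted (rows × columns), class order
low/medium/high — R_K is transposition-symmetric but precision and recall
are not. Per-class precision, recall and F-measure (harmonic mean) plus
overall accuracy (trace/total) come directly from the matrix;
division-by-zero cases yield 0 with a warning. R_K follows the
covariance form given in the README; a single observed class makes a
denominator factor vanish, and the value is then defined as 0 with a
warning. Display rounding is 3 decimals; internal values keep full
precision. On 2 × 2 matrices R_K equals the binary Matthews correlation
exactly (verified exhaustively against the closed form and scikit-learn).

The 180-trial benchmark matrix [[19,5,0],[5,50,4],[1,2,94]] reproduces
accuracy 0.906, F-measures 0.776/0.862/0.964 and high-risk recall 0.969 at
three decimals; its R_K is 0.8385, i.e. 0.839 to within one unit in the
last printed digit (exact recomputation from integer counts rounds to
0.838 — the statistic was evidently computed before the matrix was rounded
to integers).

Accuracy and R_K can rank classifiers differently — a majority-biased
matrix with accuracy 0.86 scores R_K 0.24 while a balanced one with
accuracy 0.75 scores 0.63; the pair is frozen as a test.

## Saliency

Saliency is the elementwise magnitude of ∂S_c/∂I at the input, with S_c
the **pre-softmax** class score by default (post-softmax is available but
saturates when the model is confident). For the image model the three axis
channels are reduced by max-of-absolute-values (sum available); the
sequence model yields a 36 × 750 map in raw channel order. Class averages
aggregate per-trial magnitude maps over trials whose *true* class matches
(order-invariant); single-trial maps are available. Per-placement
importance sums a placement's six rows over all frames; ties keep
placement order.

On synthetic data the trained proposed model concentrates its top-decile
saliency mass inside the two injected burst windows — the generator's
known ground truth — and the back/wrist placements dominate the sequence
model's ranking by construction of the class signatures.

## Experiment runner and pooling

`run_experiment` executes simulate → preprocess → split → train → evaluate
(→ saliency) from one YAML config; every stage seed derives from the
single global seed via `SeedSequence` spawning. Per-fold confusion
matrices are always written; the *pooled* matrix is the fold average
rescaled to one test-set size and rounded to integers by largest
remainder (the rounding loses information, hence both artifacts). Metrics
recomputed from the saved prediction CSVs reproduce the saved reports
bit-for-bit, and the run log records the defaults in effect (scaler mode,
padding convention, wrap order, filter design).

## Scaled-down benchmark sizes

The learnability checks and `scripts/acceptance.py` train the full
proposed architecture on 5 subjects × 12 zones × 3 trials (180 trials,
135/45 per fold) with `class_separation = 2.0`, `noise_sd = 0.1`, batch 8
and a 16-epoch ceiling — about 13 minutes of single-CPU training for the
four folds. Smaller designs (e.g. 72 trials) fit the training folds but
generalise poorly: with durations spanning 10–15 s the burst positions
shift across the image, and the training set must cover that range. Under
these conditions the pooled 4-fold accuracy is ≈ 0.98 and R_K ≈ 0.97,
comfortably above the 0.9 / 0.7 thresholds used in the tests.

## Known limitations

* The simulator's class structure is amplitude-based; a classifier could
  succeed here yet fail on real lifts where classes differ in subtler
  temporal patterns.
* Training on one CPU in numpy limits practical dataset sizes; the code is
  written for clarity and testability, not throughput.
* Automatic lift segmentation (start/end detection inside longer
  recordings) is out of scope; trials are assumed pre-trimmed.
* No pretraining/transfer learning, and no ImageNet-scale benchmark
  architectures: both are deliberately excluded from scope.
* The continuous scalar "model output" axis seen in swarm-plot style
  visualisations of such classifiers has no canonical definition from a
  3-way softmax and is not implemented; reports use confusion matrices.
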