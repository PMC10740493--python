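# Methods

## Scope and model overview

`semggan` implements a complete desk-scale pipeline for synthesising and
evaluating surface-EMG hand-gesture windows: a protocol simulator, signal
conditioning, sliding-window feature extraction, a per-class 1-D DCGAN, and
four statistical evaluation procedures. Everything runs on one CPU from a
single integer seed.

## Protocol simulator

Real acquisitions follow a timed protocol; the simulator reproduces two
layouts: 2000 Hz, 2 channels, 6 gestures, 3 s hold + 3 s rest, 15
interleaved repetitions (session length 6 × 15 × 6 s × 2000 Hz = 1 080 000
samples per channel); and 4000 Hz, 2 channels, 10 gestures, 5 s hold, 6
repetitions. The second protocol's rest period is not documented in its
source, so `rest_duration` is a free parameter (default 3 s).

Steady-contraction sEMG is well approximated by a band-limited stochastic
process, so each gesture class is modelled as Gaussian white noise filtered
into a class-specific band inside the 10–500 Hz sEMG passband, scaled by a
class amplitude and a trapezoidal attack/plateau/release envelope
(defaults 15 / 70 / 15 % of the hold). Default classes spread their band
centres over 60–420 Hz and amplitudes over 0.6–1.8 a.u. with seeded
per-channel jitter, which makes classes separable by both spectrum and
amplitude — learnable for classifiers and the GAN alike. Rest segments are
white noise at 5 % of the smallest class amplitude. Power-line interference
is available separately (`inject_interference`, a pure sinusoid).

What this does **not** emulate: motor-unit action-potential trains,
electrode shift, fatigue, cross-channel correlation, or session-to-session
drift. Tests passing on this generator demonstrate that the pipeline's
statistics and the GAN behave correctly on band-limited stochastic classes;
they do not certify performance on physiological recordings.

## Signal conditioning

A 4th-order Butterworth bandpass (10–500 Hz) and a second-order IIR notch
at 50 Hz (quality 30; only the centre frequency is dictated by the
application, the quality factor is a package default). Both are applied
forward–backward (`sosfiltfilt`/`filtfilt`), i.e. zero-phase, so gesture
boundaries are not delayed; the magnitude response is therefore the square
of the single-pass response, which the filter tests account for. Filtering
is applied to the whole session before windowing.

## Windowing

Window lengths 200–1000 samples by start increments of 25–100 % of the
length. "Increment" is the distance between window starts
(`step = round(length × fraction)`); a 100 % increment means non-overlapping
windows. Within a hold run of R samples the window count is
`floor((R − length)/step) + 1`. Windows are 0-based half-open
`[start, start + length)` intervals, never cross a gesture/rest boundary,
and never mix channels.

## Features

Per window: MAV, WL, MAVS, IAV, RMS, SSC, ZC, HIST and the marginal DWT.
Conventions that were genuinely open and are fixed here:

* **HIST**: B = 10 equal-width bins over the window's own [min, max]
  (per-window, not session-global); a constant window puts all T counts in
  the bin containing the value under a unit-width degenerate range.
* **SSC / ZC thresholds**: default 0, i.e. strict slope-product and strict
  sign change (`x_t·x_{t+1} < 0`); configurable.
* **mDWT**: the printed marginal-DWT formula is implemented in its standard
  form — the sum of absolute detail coefficients per decomposition level
  (Daubechies-7, 3 levels, symmetric boundary extension). The tests pin
  this to an independent cascade filter-bank oracle (extend, convolve,
  decimate per level).
* **MAVS pairing**: computed between consecutive windows inside one gesture
  run; the final window of each run is dropped so every feature row is
  complete (21 windows per run → 20 rows).

## The 1-D DCGAN

One GAN is trained per gesture class (per-class training matches the
per-gesture evaluation design; no conditional GAN). Real windows are
min-max normalised to [−1, 1] per class; the constants are stored with the
model so generated windows can be mapped back.

**Generator** — latent dimension 100 → dense projection to (C₀, L/8) → six
blocks of [nearest-neighbour ×2 upsampling (blocks 1, 3, 5)] + same-padded
conv (kernel 5) + batch norm + ReLU + dropout 0.1 → dense layer to length L
→ tanh. Output is exactly length L in [−1, 1] for any latent input.
Upsampling + convolution is used instead of transposed convolution to avoid
checkerboard artefacts.

**Discriminator** — seven conv blocks (kernel 5, strides 2,2,2,2,2,1,1,
batch norm from block 2, leaky-ReLU slope 0.2, dropout 0.25) over the raw
window, in parallel with a small two-layer conv branch over a *side-feature
vector*: one-sided FFT magnitudes (scaled by 1/√L), a DTW distance to one
real exemplar drawn per batch from a fixed reference set (scaled by 1/L),
Daubechies-7 detail coefficients, and a minibatch-discrimination similarity
scalar. The two branch outputs are concatenated into a dense head with a
sigmoid output in (0, 1).

The minibatch-discrimination summary uses a *fixed* seeded random
projection kernel (stored with the model): each sample is projected to
8 × 8 rows and scored by its mean exp(−L1) similarity to the rest of the
batch — identical batches score 1, outliers score the batch minimum. It is
a side input computed from raw signals, countering mode collapse without
adding trainable parameters.

**Gradient routing.** The adversarial gradient reaches the generator
through the raw-signal branch and through the FFT branch, for which the
exact adjoint of the one-sided FFT magnitude is implemented (interior bins
of the Hermitian spectrum halved before the inverse transform; verified by
finite differences). The DTW, wavelet and minibatch side features are
treated as stop-gradient descriptors: they sharpen the discriminator but do
not propagate into the generator. This keeps the update well-defined
(DTW's alignment path is piecewise constant) while the spectral pathway —
the most informative one for band-limited signals — stays fully
differentiable.

**Training** — alternating updates with binary cross-entropy (predictions
clipped at 1e−7). The discriminator sees the real batch with one-sided
smoothed targets (α = 0.9) and a synthetic batch at β = 0; the generator
step uses fresh latent draws against target 1 (the non-saturating form of
the minimax objective) and is computed from synthetic samples only.
Optimisers are Adam with β₁ = 0.5, β₂ = 0.999; the generator learns at
2e−4 and the discriminator at 1e−4. The half-rate discriminator is the
package's balance choice: with equal rates the discriminator dominates
early (discriminator loss → 0.17, generator saturating its tanh and
drifting to DC), while the half rate keeps both players at comparable skill
and lets the generator match the class spectrum reliably. Both rates run
flat for the first half of training and are then annealed exponentially
(halflife = epochs/20, `lr_decay=True` by default): small GANs tend to
converge to a good solution and later drift into single-mode collapse if
the adversarial game keeps running at full rate, so the schedule freezes
the converged model rather than letting it degrade. Batch size 32;
all stochastic draws (shuffling, latents, dropout, reference picks) come
from independent streams spawned from the single config seed, so training
is bit-reproducible. A non-finite loss aborts with a diagnostic state dump.

At generation time the networks run in inference mode (batch-norm running
averages, dropout off).

## Evaluation procedures

**Mantel test.** The "distance" matrices are Pearson correlation matrices
between features (zero-variance columns dropped with a warning). The
statistic standardises the n(n−1)/2 upper-triangle entries of each matrix
(ddof = 1) and averages their product over d − 1, i.e. the Pearson
correlation of the vectorised triangles; identical matrices give exactly
r = 1. The null jointly permutes rows and columns of the second matrix;
the one-sided (greater) p-value uses the +1 convention, so the smallest
attainable p at 1000 permutations is 1/1001. Identity permutations are
rejected during sampling so that bound is attained when the matrices are
equal. Reported strength bands: very weak < 0.2 ≤ weak < 0.4 ≤ medium
< 0.6 ≤ strong < 0.8 ≤ very strong (edges configurable).

**Classification.** A pluggable registry (AdaBoost, bagging, RBF-kernel
SVM, logistic regression) behind one entry point; features standardised
with training-split statistics only; stratified 80/20 split; held-out
accuracy returned. The full 36-model sweep of the original workflow is
deliberately replaced by this registry.

**Augmentation sweep.** For every (window length, increment) cell, both the
real and the synthetic source sessions are windowed and featurised
identically; synthetic rows are added at 0/25/50/75/100 % of the real
per-class counts (class-balanced within ±1, seeded selection), and the
80/20 split is stratified by (class, origin) so the test set mirrors the
mixed composition. The 0 % cell calls the exact same split/fit routine as
plain classification, making the identity bit-for-bit under a shared seed.
An optional per-cell row cap subsamples real windows (class-balanced) to
bound runtime on large grids.

**C2ST.** Real rows are labelled 1 and generated rows 0; the pooled set is
shuffled, split 80/20, standardised on the training split and classified by
logistic regression (the margin classifier with finite norm). The test
statistic is the held-out accuracy; 0.5 means the samples are
indistinguishable. Scaling before the logistic fit is a numerical aid only
— under the null it cannot create separation.

## Numerical and design notes

* Window steps, counts and durations are exact integer arithmetic; the
  1000-sample window maps to 500 ms at 2000 Hz and 250 ms at 4000 Hz.
* The DTW recurrence (|aᵢ−bⱼ| local cost, full window) is a plain dynamic
  program, numba-compiled when available; a memoized-recursion oracle pins
  its values in the tests.
* Problem sizes in the test suite are deliberately modest — e.g. the
  trainability check trains 200 epochs on 128 windows of length 256 and the
  augmentation grid caps rows per cell — chosen so the whole suite runs on
  one CPU in well under half an hour while still exercising every code
  path at realistic signal scales.
* Degenerate inputs fail loudly: empty windows, constant windows for
  normalisation, single-class classification, zero-variance Mantel
  triangles, non-finite training losses.

## Known limitations

* The simulator's classes are stationary within a hold; real sEMG is not,
  and GAN quality on real recordings will differ.
* GAN convergence is seed-sensitive at this scale: the narrowband
  trainability check holds at its fixed seed, but other seeds can converge
  to neighbouring spectral modes. Averaging over many seeds would need
  longer budgets than a desk-scale suite allows.
* At desk scale the generated windows remain *detectably* synthetic: a
  classifier two-sample test against the training class saturates near
  accuracy 1.0 (the amplitude distribution and spectral width are narrower
  than the real class). Class identity is therefore demonstrated through
  spectral statistics (peak location, mean-spectrum distance) rather than
  through C2ST orderings, and C2ST is most informative in this package as
  a *null* calibration instrument and as a relative quality score.
* The GAN is numpy on one CPU: suitable for windows up to ~1000 samples and
  hundreds of epochs, not for large-scale replication.
* Side features enter the discriminator through one fixed concatenation
  point; alternative wirings (e.g. per-feature branches) are plausible and
  config-exposed only through the branch widths.
* The Mantel and C2ST procedures assume exchangeable windows; strongly
  overlapping windows violate independence, which inflates the effective
  sample size of both tests (windows at 25 % increments share 75 % of
  their samples).
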