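# Methods

This note documents the models and procedures implemented in `eegmusic`, the
parameter choices that matter, and what the synthetic experiments do and do
not demonstrate.

## Synthetic EEG generator

Each experimental condition is a `ConditionProfile`: relative power weights
for the five clinical rhythms (δ 0.5–4, θ 4–8, α 8–13, β 13–30, γ 30–45 Hz)
and a *regularity* scalar in [0, 1].  A recording is built from
`max(1, n_channels − 2)` latent cortical sources; each source is, per
rhythm, the unit-power mixture

    sqrt(r) · sinusoid(f_center, slowly jittered phase) + sqrt(1 − r) · band-limited noise

scaled by the square root of the normalized band weight.  Channels are
unit-norm random mixtures of the sources (volume conduction), so every
channel carries the profile's band-power fractions exactly; the overall
scale is ~20 µV RMS.  Modelling channels as mixtures of a few shared
sources, rather than as independent processes, is deliberate: scalp EEG is
strongly spatially correlated, and it is precisely this low-rank structure
that makes ICA-based artifact rejection work, on real data as here.  An
optional independent per-channel sensor-noise floor exists
(`sensor_noise`, fraction of signal power) but defaults to zero because
contamination is modelled explicitly by `ArtifactSpec`; note that already a
0.1%-power floor makes the source model overcomplete and measurably degrades
ICA separability.

Artifacts: blinks are smooth unipolar 0.3-s Hann bumps arriving as a Poisson
process (default 12/min, 80 µV) with the fixed frontal topography
(1.0, 0.8, 0.3, 0.1) cycled over channels; mains interference is a common
sinusoid (default 50 Hz, 10 µV).  All draws happen in a documented order
from `default_rng(seed)`, so e.g. the blink count is exactly recomputable.

Cohorts derive per-subject gains (±20%) and per-recording seeds
deterministically from one master seed via `SeedSequence`; there is no
hidden global randomness anywhere in the package.

**Default study conditions**: 28 subjects × 5 conditions, 60 s per
recording, 256 Hz, 4 channels; the five default profiles give condition *i*
a 6:1 weight advantage in rhythm *i* and spread regularity over
0.2 … 0.8, so conditions differ both spectrally and in signal regularity.

## Denoising

`denoise` runs two stages:

1. **FastICA artifact rejection.**  Centering, eigen-whitening (reducing to
   the effective covariance rank with a warning when deficient), then the
   symmetric fixed-point iteration with the tanh contrast
   (tol 1e-5, ≤500 iterations; non-convergence returns the best iterate
   flagged).  Components are ordered by explained channel-space variance
   with signs fixed so the largest mixing weight is positive.  A component
   is flagged as artifact if (a) its excess kurtosis stands out — robust
   z-score over components, (k − median)/max(1.4826·MAD, 1) > 2.5 — or
   (b) ≥ 60% of its periodogram mass lies within ±1 Hz of the configured
   line frequency.  The MAD floor of one excess-kurtosis unit matters: with
   a 4-channel montage there are only 4 components, and an unfloored MAD
   routinely inflates the z-score of mildly spiky brain components.
   Flagged components are zeroed and the rest back-projected.
2. **Hilbert–Huang cleaning per channel.**  Classic sifting EMD
   (cubic-spline envelopes through the extrema, ends mirror-extended by 3
   extrema; Cauchy SD stopping criterion 0.2; ≤10 IMFs), then the analytic
   signal of each IMF gives its instantaneous frequency; IMFs whose median
   instantaneous frequency falls outside 0.5–45 Hz are dropped along with
   the residue (sub-δ drift) before reconstruction.

**Stage order.**  ICA runs *before* the per-channel EMD on purpose.  A 10 µV
mains line dominates the first intrinsic mode (median instantaneous
frequency ≈ 46–50 Hz), and the >45 Hz drop rule would then discard the β/γ
activity mixed into that mode — EMD cannot split 50 Hz from 30–45 Hz, as the
frequency ratio is below its ~2 octave resolution.  Removing the spatially
coherent artifacts first costs almost nothing (they live in their own
independent components) and leaves the EMD stage a line-free signal on which
the drop rule removes only drift and supra-γ content.  Measured on the
default conditions, the combination removes >99% of line-band power, leaves
artifact-free recordings with per-channel correlation ≥ 0.98 to the input,
and is near-idempotent (second application changes < 8% RMS).

Single-channel recordings skip ICA (logged warning).  The replacement of any
learned artifact detector by these two statistical flags is a deliberate
design decision of this package.

## Features

The **harmonic wavelet packet transform** is implemented in its defining
(Newland) form: harmonic wavelets are ideal boxcar filters in frequency, so
the transform partitions FFT bins into the five rhythm bands (plus a
remainder band covering the rest of [0, f_N]) and inverts each partition.
Because the partition is exact, Parseval's identity holds to machine
precision (measured ≤ 1e-12 relative) and band energies are exactly
orthogonal: adding an α tone changes δ-band energy by nothing.

Per epoch (default 4 s, non-overlapping):

* **25 FBER values** — 5 equal non-overlapping sub-windows × 5 rhythms
  (window-major order); each sub-window's five percentages sum to 100
  exactly.
* **25 sliding-average SampEn values** — 25 half-overlapping windows
  spanning the epoch; SampEn(m=2, r=0.2·SD, Chebyshev distance,
  Richman–Moorman conventions with self-matches excluded, both template
  counts over the N−m extendable templates); the "sliding average" is the
  running mean of the current and previous window (first window passes
  through).  The vectorized counter is tested for *exact* count equality
  against an O(N²) double-loop oracle.

Channel handling: per-channel 50-vectors are averaged across channels
(per-channel mode available).  Columns are z-scored using training-row
statistics only, and only once a train/test split exists — test rows never
influence the scaling.  Epochs whose features fail (zero-variance window,
infinite SampEn) are dropped with a logged reason.

**Limitations worth knowing.**  At m=2 and 256 Hz, SampEn is driven by
sample-scale predictability.  The regularity→entropy contrast is therefore
reliable when one rhythm dominates (verified: regularity 0.9 < 0.1 in
SampEn on 20/20 seeds for an α-only profile at 8-s epochs) but *not* for
broadband multi-rhythm profiles: a sum of five incommensurate tones is a
five-torus orbit whose embedding is genuinely complex, and its SampEn can
exceed that of equally-loud noise.  Similarly, because r scales with the
signal SD, SampEn saturates at the noise's own entropy once additive noise
dominates; monotonicity in noise level is a pre-saturation property.

## Classifier

`DBNClassifier` follows the canonical deep-belief-network recipe, chosen for
verifiability:

* **Pretraining**: greedy layer-wise CD-1 (k configurable), learning rate
  0.05, 15 epochs.  The first RBM has Gaussian visible units (features are
  real-valued z-scores; visible reconstruction is the linear mean); deeper
  RBMs are Bernoulli and consume the propagated hidden probabilities.
  Correctness is established at enumerable scale: on a 4-visible/3-hidden
  RBM the exact data log-likelihood (brute-force partition function over all
  2⁷ states) strictly increases over 500 CD-1 epochs, and the CD-1 update
  direction has positive cosine to the exact likelihood gradient.
* **Fine-tuning**: softmax head (max-subtracted, shift-invariant) on the top
  hidden layer; cross-entropy loss; full-batch gradient descent (lr 0.5, 500
  iterations, seeded reshuffle each iteration; momentum/weight-decay
  available but off by default).  All analytic gradients are verified
  against central finite differences.  The per-iteration **MSE trace** is
  the Brier-style mean over training rows of Σ_j (p_j − 1{y=j})²; with 5
  classes it starts at 0.8 for an untrained uniform classifier.  A
  non-finite loss aborts fine-tuning, returning the last finite state.
* **Architecture default** 50-40-30 with a 5-way softmax.  Ties in the
  argmax go to the lowest class index.  The full fit is bit-reproducible
  from `TrainConfig.seed`.

Train/test split: stratified by condition within subject, 72%/28%, seeded.

## Reporting

The confusion matrix is reported both as raw counts and row-normalized
percentages (rows = true condition; each non-empty row sums to 100; the
diagonal is each condition's accuracy and is appended as an "Accuracy" row
in the display layout).  Per-subject accuracy comes with its
(mean, min, max) summary.  The band-energy group comparison is a per-rhythm
Welch (unpaired) or paired t-test, two-sided, with an optional Bonferroni
flag (off by default).  The transient-frequency profile compares two
conditions' median amplitude²-weighted instantaneous-frequency curves; ties
count half in the dominance fraction, so a self-comparison is exactly 0.5.

## Problem sizes and determinism

The reference cohort experiment (28 subjects × 5 conditions × 60 s at 256 Hz,
~2 100 epochs, 500 fine-tuning iterations) is the package's reference
experiment; it is generated artifact-free with denoising disabled, since its
purpose is class recovery (denoising quality is measured separately on
20-s contaminated recordings).  Everything — simulation, splits,
pretraining, fine-tuning — derives from a single seed, and two runs with the
same configuration produce byte-identical report files.

## What passing synthetic tests does not show

The generator makes no attempt to model depression-specific EEG pathology,
medication effects, inter-subject montage differences, non-stationarity
within a recording, or realistic artifact diversity (muscle, electrode pops,
sweat drift).  Class separability is a controllable simulation parameter;
recovering it demonstrates that the pipeline is implemented correctly, not
that any particular accuracy is attainable on clinical recordings.
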