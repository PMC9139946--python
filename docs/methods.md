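# Methods

`pdcsp` implements a common spatial pattern (CSP) pipeline for two-class
classification of multichannel resting-state EEG, aimed at separating
Parkinson's disease recordings (off- or on-medication) from healthy
controls. This note documents the model, the numerical choices, the
synthetic data the tests run on, and the limits of what those tests show.

## Pipeline

A recording is a `ch x samples` matrix at sampling rate `fs`. The chain is:

1. **Band-pass filtering.** A fifth-order Butterworth band-pass (default
   10–30 Hz, covering the upper alpha and beta bands) applied
   forward–backward (`scipy.signal.sosfiltfilt`). Zero-phase filtering
   doubles the effective roll-off and avoids phase distortion across
   channels, the standard choice for offline EEG analysis; the `order`
   parameter refers to the one-pass design. Causal filtering would be the
   alternative for online use; it is not provided.
2. **Segmentation.** Consecutive non-overlapping windows of
   `N = floor(T * fs)` samples (default `T = 2` s). Trailing remainders
   are dropped, so recordings of unequal length contribute unequal segment
   counts. Segments are the unit of classification.
3. **CSP.** See below. Fit per cross-validation fold on training segments
   only; the reduced `d x ch` projection is frozen and applied to the test
   fold.
4. **Features.** One of eight functionals maps each filtered `d x N`
   segment to a length-`d` vector (below).
5. **Classification.** Random forest (100 trees), LDA, QDA, quadratic-kernel
   SVM (`C = 1`), or k-nearest neighbours (`kn = 3`, Euclidean), evaluated
   with stratified 10-fold cross-validation. Accuracy, sensitivity,
   specificity, precision and F-score are computed per fold from the
   confusion counts (percent scale) and reported as mean ± standard
   deviation across folds, together with the fold ROC curves and
   trapezoidal AUC. The patient group is the positive class, so
   sensitivity is patient detection. Tree count and SVM regularisation are
   conventional defaults, configurable.

## The CSP model

For class-averaged, trace-normalised spatial covariances `C_A`, `C_B`
(per-segment `E E' / trace(E E')`, arithmetic mean within class):

- eigendecompose the composite `C_C = C_A + C_B = U diag(l) U'`
  (eigenvalues descending);
- whiten with `P = diag(l)^(-1/2) U'`, so `P C_C P' = I`;
- eigendecompose the whitened class-A covariance `S_A = P C_A P' = B D B'`
  (descending). Because `S_A + S_B = I`, the class-B eigenvalues are
  `1 - D` on the same eigenvectors: the component that maximises class-A
  variance minimises class-B variance and vice versa;
- the projection is `W = B' P`; rows are spatial filters. Retaining the
  first and last `m` rows gives the reduced projection with reduction
  number `d = 2m` (default `d = ch`, i.e. no reduction).

The `-1/2` whitening exponent is the only choice under which the
eigenvalue sum identity holds; it is asserted to `1e-8` in the tests.

Numerical choices:

- **Mean centering.** Each segment's per-channel mean is removed before
  the covariance (configurable). Band-passed signals are already near
  zero-mean, so this is a small correction; it makes the scatter matrix a
  true covariance.
- **Determinism.** Eigenvalues are sorted descending; each filter row is
  sign-flipped so its largest-magnitude entry is positive. CSP is
  sign-invariant downstream, so this is purely a canonicalisation making
  refits bit-identical. Repeated eigenvalues leave filters non-unique
  within the degenerate subspace; tests avoid exact ties.
- **Rank deficiency.** A composite covariance with an eigenvalue below
  `1e-10 x` its largest raises an error by default. An opt-in
  `on_singular="regularize"` floors the spectrum by `1e-10 x max`;
  the hard error is the default because silent regularisation can mask
  broken inputs (e.g. a dead channel).

## Feature functionals

All functionals operate on the raw samples of each spatially filtered
component `s_j(n)`, `n = 1..N`; logs are natural.

| name | definition |
|---|---|
| VAR | `log(var(s_j) / sum_j' var(s_j'))`, population variance |
| BP | `log(mean(s_j^2))` |
| ENG | `sum(s_j^2)` |
| THEN | `#{n : abs(s_j(n)) > alpha}`, default `alpha = 0.2` |
| NOEN | `sum(abs(s_j)^p)`, default `p = 1.1` |
| SUEN | `N - #{abs(s_j) <= q} + sum(min(s_j^2, q^2))`, default `q = 3` |
| LOGEN | `sum(log(s_j^2))`, zero samples contribute 0 |
| SHEN | `sum(s_j^2 log(s_j^2))`, zero samples contribute 0, sign as written |

Design choices here were genuinely open:

- The entropy family is evaluated on amplitudes (the wavelet-entropy
  convention), not on a probability histogram of unique values: the
  thresholds `alpha = 0.2` and `q = 3` are amplitude thresholds that would
  be meaningless for probabilities bounded by 1, and `min(x^2, q^2)` only
  makes sense on signal amplitudes. Consequently THEN/NOEN/SUEN (and the
  zero-conventions of LOGEN/SHEN) are *scale-dependent*: they operate on
  whatever units the input uses. The package never rescales data, so
  amplitude units are the caller's contract.
- SHEN keeps the positive sign (no leading minus). Any monotone
  relabelling of a feature is irrelevant to every classifier used here.
- `log(0)` terms contribute 0, keeping LOGEN/SHEN finite on exact zeros.
- VAR uses the population convention (divide by `N`), consistent with the
  covariance normalisation.

## Cross-validation and leakage

Folds are stratified by class with a fixed seed. The CSP projection is
refit inside every training fold; tests assert (by corrupting test folds
with sentinels) that the projection never sees test data. Segment-level
cross-validation follows common practice in this literature but lets
segments of one subject appear in both partitions, which inflates
accuracy relative to subject-level generalisation; `cv_mode="subject"`
provides a subject-blocked split (grouped stratified folds) for an honest
estimate. Neither mode is claimed to reproduce any published protocol.

A class with fewer than `k` members triggers a warning and an
unstratified fallback split.

## Synthetic data

The generator plants exactly the structure CSP assumes and nothing more:
stationary band-limited Gaussian sources mixed into channels by a random
orthogonal matrix `A` (QR of a Gaussian matrix, sign-fixed for
uniqueness), plus band-limited Gaussian sensor noise:

`x(t) = A s(t) + n(t)`

The first `n_discriminative` sources have their variance multiplied by
`1 + separation` and the last divided by it for class A; class B is the
mirror image. `separation = 0` makes the classes identical. Defaults — the
study conditions for the tests and the acceptance script — are 8 channels
at 256 Hz, 4 recordings per class of 100 s each (200 two-second segments
per class), `separation = 4`, sources band-limited to 10–30 Hz, sensor
noise with standard deviation 0.2 (relative to unit source variance)
band-limited to 1–45 Hz. The wider noise band means out-of-band analysis
bands contain noise only, which is what a band sweep on real EEG would
encounter; 0.2 was chosen once as a realistic sensor-noise floor well
below the source power.

Closed-form class covariances are available
(`theoretical_covariances`): `g_s A D A' + g_n sigma^2 I`, unit-trace,
where the `g` factors are the white-noise power gains of the two
band-limiting filters (frequency average of `|H|^4`, since filtering is
forward–backward). These serve as exact targets for covariance-recovery
tests.

What passing on this generator shows: the algebra, the plumbing, and the
statistical machinery are correct, and the pipeline recovers planted
spatial structure (first filter aligned with the true unmixing direction,
cosine ≥ 0.95 at the default conditions). What it does not show: anything
about real EEG, which has 1/f spectra, artifacts, nonstationarity,
volume-conduction structure and subject heterogeneity that the generator
deliberately omits.

## Problem sizes

Tests and the acceptance script run at 8 channels with 100–400 segments,
chosen as the smallest sizes at which the Monte-Carlo checks (covariance
convergence within Frobenius 0.05, chance-level bands of ±10 points) are
stable across seeds. The reduction-number sweep uses
`separation = 0.8, noise_std = 1.2, n_discriminative = 3`, a regime where
discriminative variance is spread over six spatial components so the
accuracy-vs-`d` curve genuinely rises before it plateaus.

## Known limitations

- Two classes only; no multi-class CSP extension, no shrinkage/regularised
  CSP variants.
- No artifact detection or rejection; inputs are assumed pre-cleaned.
- Entropy thresholds are not adaptive to signal scale (see above).
- EDF/BDF reading is supported (via MNE); writing those formats is not.
- The sweep drivers parallelise nothing; runs are sequential by design
  (reproducibility over speed).
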