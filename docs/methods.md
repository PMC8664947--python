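# Methods

This note documents the models, conventions and numerical choices
behind `hypnostats`, in the order the pipeline runs.

## Data model and time scales

Three nested time scales organize everything:

1. **Samples** `t` — raw EEG amplitudes `y_k(t)` in µV at 256 Hz
   (configurable), channels `k` (default `F4-M1, C4-M1, O2-M1`).
2. **Epochs** `n` — non-overlapping 30-s windows (7680 samples at
   256 Hz), the unit of sleep scoring.  Epochs are half-open sample
   windows `[n·L, (n+1)·L)`; a trailing partial epoch is dropped.
   Epoch indexing is 0-based everywhere.
3. **Phases** `J` — maximal runs of consecutive epochs with the same
   stage label; phases tile the hypnogram.

The stage alphabet is fixed as `(Wake, REM, N1, N2, N3)` and this order
is used in every probability vector and transition matrix.  Wake is
treated as a stage for convenience.

## Per-epoch statistics (`epochs`)

* **Moments.**  STD, excess kurtosis and skewness use population
  normalization (divide by N, no small-sample correction), matching
  their definition as plain time averages.  A constant segment returns
  STD = 0 with KUR/SKE/ACF flagged `NaN` (undefined), never an
  exception at table level.
* **ACF/CCF.**  The biased estimator divides the lagged sum by the full
  segment length, which guarantees `ACF(0) = 1` and keeps the curve
  bounded; the cross-correlation uses each channel's own mean and
  population STD.  Zero-variance segments raise
  `UndefinedStatisticError`.
* **The 300 ms lag.**  300 ms at 256 Hz is 76.8 samples.  The nearest
  integer lag (77 samples ≈ 300.8 ms) is used; `acf_lag_samples`
  exposes the realized lag.
* **Histograms.**  Per-epoch amplitude densities share one symmetric
  bin grid (201 bins, range ± the 99.99th percentile of the pooled
  absolute amplitudes) so stage averages live on a common axis.
* **Pooling.**  Curves (histograms, ACFs) are *averaged* with equal
  weight per unmasked (epoch, channel) pair; hyper-parameters are
  *pooled* (concatenated, not averaged) into per-stage sample sets.

Oracle tests check all estimators against brute-force evaluation of the
defining sums to 1e-12 on short segments.

## Stage-conditional likelihoods (`distributions`)

`q(h | s)` is built per stage and hyper-parameter from the pooled
samples:

* **Histogram basis.**  50 bins (default) on a range shared across
  stages — the pooled [0.5th, 99.5th] percentile span — so stages are
  directly comparable.  Stages with < 30 samples trigger a warning and
  wider bins for that hyper-parameter.
* **Continuous evaluation.**  Log-density is interpolated linearly
  between bin centers (so the midpoint of two bins evaluates to the
  geometric mean of their densities).  Within the outer half of the two
  edge bins the edge density is held constant.  Beyond the occupied
  support, log-density is extrapolated linearly from the two outermost
  non-empty bins; when fewer than two occupied bins exist, or when the
  empirical two-bin slope fails to decay outward, the tail instead
  decays from the edge density to the floor over one bin width.  This
  keeps the tail monotonically non-increasing away from the support.
* **Positivity.**  Every density is floored at `ε = 1e-12` (in the
  hyper-parameter's density units), keeping log-likelihoods finite for
  arbitrary outliers.  A log-linear construction was chosen over
  unconstrained spline fits precisely because splines can go negative,
  which the Bayesian update cannot tolerate.  A Gaussian-KDE variant is
  available (`method="kde"`); it is not serializable.
* **Serialization.**  Histogram models round-trip through a single
  JSON document (edges, densities, floor), so classifier runs are
  reproducible without refitting.

## Transition matrices (`markov`)

Epoch-level `M(s_{n+1} | s_n)` and phase-level `M(s_{J+1} | s_J)`
matrices are maximum-likelihood row normalizations of pooled transition
counts, with optional add-α smoothing (default 0 for estimation; the
pipeline uses α = 0.5 for the classifier prior so unseen transitions
are never impossible).  Counts are pooled across recordings and never
cross a recording boundary.  Artifact-masked epochs keep their scored
label and still contribute transitions.  Rows without observations stay
zero and are flagged rather than invented.  The phase-level diagonal is
structurally zero.  Per-subject matrices (averaging instead of pooling)
can be obtained by estimating per recording and averaging externally.

## Bayesian stage filter (`bayes`)

A forward filter, no backward pass and no Viterbi decoding:

* Prior: previous posterior propagated through the epoch matrix,
  renormalized.  Stages with exactly zero prior keep exactly zero
  posterior (an absorbing point-mass prior stays absorbing); all other
  products run in the log domain.
* Likelihood: product of `q(h | s)` over the selected hyper-parameters
  (default STD, KUR, SKE).  Hyper-parameters are averaged over channels
  per epoch before the lookup (`channel_policy="average"`); requesting
  a hyper-parameter absent from the table or the model fails loudly.
* Initial epoch: point mass on Wake (lights-off assumption); a uniform
  start is available.
* Artifact epochs (and epochs with undefined hyper-parameters) are
  updated with the prior only.
* Evaluation: `accuracy` is the fraction of correct MAP labels over
  unmasked epochs.  `accuracy_by_subset` fits the likelihood model and
  (unless supplied) the transition matrix on the *other* recordings
  (leave-one-recording-out) before scoring each recording, keeping
  training and test data disjoint; with a single recording it falls
  back to in-sample fitting.

## Trends (`trends`)

* **Cycle direction.**  Wake and N3 — the cycle extremes — get
  direction `none`.  A REM/N1/N2 phase scans the phase sequence
  forward: N3 ahead before any Wake means *falling*, Wake first means
  *rising*.  If neither lies ahead, the backward scan is used with the
  roles swapped (most recently preceded by Wake → falling, by N3 →
  rising).  Phases neither scan resolves are excluded from directed
  aggregation.  This scanning rule is a construction of this package.
* **Slopes.**  OLS of the channel-averaged hyper-parameter against the
  epoch *index* within the phase (masked epochs are dropped from the
  fit but do not compress the time axis).  The reported intercept is
  the fitted value at the phase start.  Phases with fewer than two
  usable epochs are skipped.
* **Aggregation.**  Mean slope per directed stage, rows ordered
  Wake, REM↓, N1↓, N2↓, N3, N2↑, N1↑, REM↑; the error is the standard
  error of the mean over phases (NaN for a single phase); empty cells
  are reported missing, not zero.

## Separability (`separability`)

* **GDV** applies the z-score-and-halve rescaling (population STD;
  constant dimensions dropped with a warning) and compares mean
  intra-class with mean pairwise inter-class Euclidean distances,
  scaled by `1/√D`.  Two coincident-point classes in 1-D give exactly
  −1.0 at any separation.  Negative = separated; the stage matrix
  reports |GDV| so both matrices read "larger = more distinct".
* **CSI** works on raw coordinates (its ratio form is scale- and
  translation-invariant by construction): the mean over points of
  `ln(d_nearest_other / d_nearest_same)`.  Duplicate points make a
  nearest-neighbor distance zero and raise an error; an explicit
  `jitter` option perturbs coordinates by a documented fraction of the
  coordinate scale instead (the stage matrix uses `1e-9`).
  Nearest-neighbor ties are irrelevant: only the minimal distance value
  enters the ratio.
* The two measures are deliberately complementary: the GDV's all-pairs
  averaging penalizes elongated clusters, so two dense parallel
  line-like clusters score near zero on |GDV| but clearly positive on
  the CSI.
* A documented anomaly: the often-quoted calibration that two Gaussian
  clusters whose mean separation equals twice their STD give GDV = −1.0
  does not follow from the defining sums (it holds for point-like
  clusters); the equations are implemented as defined and no Gaussian
  recalibration is applied.

## Synthetic generator (`synthetic`)

A two-level surrogate with analytically known statistics:

* **Second level.**  A first-order Markov chain over the five stages
  produces the hypnogram.  The default matrix is diagonal-dominant
  (persistence ≈ 0.85–0.93 per epoch) with the canonical progression
  Wake → N1 → N2 → N3, N2↔N3 oscillations and REM entered from N1/N2.
* **First level.**  Within each epoch, AR(1):
  `y_t = φ y_{t-1} + ε_t`, innovations standardized Student-t
  (`tail_dof`), optionally skewed by a two-sided scale asymmetry
  (positive/negative draws scaled by `exp(±skew_coefficient)`, then
  re-standardized analytically so the innovation scale contract is
  unaffected), with innovation scale
  `base_scale × scale_multiplier × exp(τ·G_b)` where `G_b` is one
  standard normal per 0.25-s block (64 samples).  The block-wise
  log-normal modulation is the super-statistical mechanism that
  produces large excess kurtosis.  The recursion starts from a draw
  with the stationary scale, so per-epoch moments carry no startup
  transient.
* **Closed forms used in tests.**  Stationary AR(1) ACF is `φ^ℓ`;
  innovations with excess kurtosis `κ_ε` give signal excess kurtosis
  `κ_ε(1-φ²)/(1+φ²)`; for `φ = 0` and Gaussian innovations the
  modulation alone gives `3(e^{4τ²} - 1)`.
* **Trends.**  Within each contiguous same-stage run the per-epoch
  scale multiplier evolves geometrically by `(1 + trend_per_epoch)`
  per epoch, resetting at each phase start.
* **Artifacts.**  Epochs are flagged with probability `artifact_rate`
  and overwritten with a saturated square burst at 5× the stage's base
  scale (0.5-s period) — trivially detectable, and exercising the
  prior-only update path of the filter.
* **Defaults.**  Stage amplitude scales 10/25/60/140/300 µV from Wake
  to N3 (a monotone ladder mirroring the physiological progression
  towards large slow waves, and keeping stage clusters separated in
  STD), AR coefficients 0.95–0.985 (N3 most correlated, ACF decaying
  over a few hundred ms), `tail_dof` 6–10, `variance_mod_sd = 0.2`,
  small stage-dependent skews.  Note `base_scale` is the *innovation*
  scale: the stationary signal STD is `base_scale/√(1-φ²)`, so the
  realized per-stage STDs are about 33/90/215/575/1790 µV.  All
  presets are conventions of this package, not fits to clinical data.
* **Reproducibility.**  One pseudo-random stream per recording,
  derived from the single seed; output is bit-reproducible.

**What the generator does and does not emulate.**  It reproduces the
amplitude-statistics phenomenology: stage-dependent leptokurtic
amplitude distributions, short-range autocorrelation, within-stage
hyper-parameter fluctuations and trends, Markov stage dynamics, and
artifact epochs.  It contains no oscillatory structure (no alpha
rhythm, spindles or K-complexes), no 1/f background, no inter-subject
variability, and its stages are far more separable in STD than real
sleep stages are.  Passing tests therefore demonstrate estimator and
pipeline correctness — not clinical staging performance; accuracies on
these surrogates are upper bounds of a very idealized regime.

## Problem sizes and tolerances

* Exact arithmetic checks (brute-force oracles, worked CSI/GDV values)
  use ≤ 50 points/samples and tolerance 1e-12.
* Monte-Carlo recovery of the generator's closed forms uses 16
  independent streams of 48 000 samples (7680 × 100 in total) per
  experiment and 3 standard errors; kurtosis recovery uses pooled
  central moments with a jackknife standard error over streams, which
  avoids the downward ratio bias of per-epoch kurtosis estimates when
  the number of modulation blocks per epoch is small.
* Markov round trips use ≥ 10⁴ simulated epochs and 3 binomial SEs.
* Classifier evaluation uses 6 surrogate nights × 220 epochs with
  leave-one-night-out fitting; trend recovery uses one 500-epoch night
  with a 5%-per-epoch N2 trend, modulation switched off, and a 3-SEM
  criterion against the generator's own mean slope.
* Posterior vectors must sum to 1 within 1e-9; transition-matrix rows
  within 1e-12.

## Known limitations

* The filter is strictly causal (filtering, not smoothing); accuracy
  near stage transitions is limited by the one-epoch prior lag.
* The likelihood factorization over hyper-parameters assumes
  conditional independence given the stage, which is only approximate
  (STD and KUR of the same epoch are correlated).
* Linear common-range binning allocates few bins to low-amplitude
  stages when scales span orders of magnitude; the tail conventions
  above keep this benign, but strongly imbalanced scale ladders reduce
  likelihood resolution for the smallest stages.
* EDF files are read (via `mne`) but not written; recordings are
  written as delimited text.
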