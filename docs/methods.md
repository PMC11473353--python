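# Methods

This note documents the models, estimators and design choices behind
socimotor, in the spirit of a statistical-software methods appendix:
what is computed, under which assumptions, with which defaults, and
what the synthetic benchmarks do and do not demonstrate.

## Micro-movement spike normalization

The pipeline operates on the scalar angular speed, the Euclidean norm
of the triaxial gyroscope channels (deg/s).  Peaks are interior local
maxima under a first-of-plateau tie rule (the first sample of a flat
maximal run is the peak; symmetrically for valleys), which makes the
extraction deterministic on data with repeated values.  Each peak's
deviation is measured from the *session-level* Gamma-MLE mean of the
speed series — the person's empirical baseline — rather than from
per-window means, so windows of one session share a single reference.
The normalized amplitude is

    norm_peak = peak_dev / (peak_dev + avg_min_dev),

with `avg_min_dev` the mean of the two flanking local minima's
deviations.  Peaks at the series edges are discarded (no flank on one
side); when a peak has no interior valley toward one edge, the edge
sample itself serves as the flank (it is necessarily lower than the
peak on a monotone run).  A peak whose numerator and denominator are
both exactly zero is a quiet moment and maps to 0 with a warning.
An alternative reading of the flank term — the mean of *all* samples
between the two minima — is selectable with
`RunConfig(mms_flank_mode="min_to_min_mean")`; the two-minima average
is the default because the normalization is stated in terms of the
local minima.  An optional amplitude floor
(`RunConfig.amplitude_floor`, default 0: keep everything) can drop
sub-threshold peaks before binarization.

The key property, asserted to 1e-9 in tests, is scale invariance:
multiplying the whole speed series by any c > 0 leaves every
normalized value unchanged, which is what removes allometric
(anatomy-driven) amplitude differences between people.

## Gamma process, NSR and control

MMS amplitudes are fit with the two-parameter Gamma family by maximum
likelihood: Newton iteration on the digamma score equation
`log k − ψ(k) = log(mean) − mean(log x)`, initialized at the
method-of-moments estimate, tolerance 1e-10, at most 100 iterations.
Exact zeros are excluded (Gamma support is positive; zeros are
baseline quiet moments) with the count recorded on the fit.  The fit
floor is 30 positive samples by default; windows below the floor
yield missing features rather than errors.  Confidence intervals come
from the observed Fisher information (per-observation matrix
`[[ψ′(k), 1/θ], [1/θ, k/θ²]]`); a seeded nonparametric bootstrap is
available as `ci_method="bootstrap"`.  Moments are stored as
`μ = kθ`, `σ² = kθ²`, `skew = 2/√k`, so the identities hold by
construction, and `nsr()` returns the scale itself — the value that
σ²/μ reduces to algebraically.  (An IEEE division (kθ·θ)/(kθ) is not
always bit-identical to θ, which is why the reduction is returned
directly; the division agrees to well below 1e-9 and is asserted in
tests.)  The control index is −log(θ) in the configured base
(default 2, so bits, consistent with the entropy units).

The maturation power law is an ordinary least-squares fit of log k on
log θ across sessions or tasks (at least 3 points), reporting
intercept, exponent with its 95% CI, residual standard error and R².

## Entropy-rate (autonomy) estimation

Approximate entropy implements the count-ratio estimator: with
templates of length m and m+1 compared under Chebyshev distance < r
over the same N−m positions (self-matches included, so every ratio is
defined), ApEn is the mean of log(C_m/C_{m+1}) in the configured base.
A constant series gives exactly 0.  On data whose distinct values are
at least r apart (binary spike trains with the default r = 0.5),
matching reduces to exact symbol equality and an O(N) word-encoding
path replaces the O(N²) scan; both paths are tested against a literal
double-loop oracle.  The template length defaults to the rounded mean
inter-spike interval of the session train, capped at 10 (the cap
guards against degenerate undersampling on very sparse trains and is
logged when hit); the intent is that a template typically spans both
quiet samples and a spike.  On binary data the estimate is bounded by
1 bit up to estimator slack.

Windows are contiguous, non-overlapping, half-open spans of 1000
samples (7.8125 s at 128 Hz) — short enough to treat the train as
locally stationary, long enough for stable counts; trailing partial
windows are dropped and logged.  The autonomy variability of a
session is the sample variance (n−1 denominator, appropriate for the
small window counts) of per-window ApEn divided by its mean.  The
agency ratio is autonomy mean over session control, reported as
undefined (NaN, flagged) when the control index is 0.

The embedding delay feature is the first strict local minimum of the
average-mutual-information curve (equal-width 16-bin histogram
estimator; exact symbols when the series takes few values; lag-0 AMI
serves as the left boundary), falling back to the argmin with a
warning when no local minimum exists within the lag horizon.  It is
computed per window on the max-normalized continuous speed, not on
the binary train.  Note that the binned AMI curve of strongly
periodic noiseless signals aliases with the bin count (a pure sine at
16 bins shows a rippled curve whose minimum can land a few samples
off the quarter period); on noisy physiological data, which is what
the feature is for, the curve is smooth and the rule behaves as
intended.

## Transfer entropy

All transfer-entropy quantities are plug-in estimates over
integer-encoded words: target future, k-deep target history and
l-deep source history (defaults k = l = 20).  The local TE of each
transition is `log p(x⁺|x_k, y_l) − log p(x⁺|x_k)` under pooled
empirical counts; the average TE is their mean, which equals the
conditional mutual information `I(x⁺; y_l | x_k)` of the empirical
distribution and is therefore non-negative; and the decomposition
`TE = h_X − h_{X,Y}` (conditional entropy rate minus the
source-conditioned generalized entropy rate) holds to floating-point
rounding because all three quantities are different groupings of the
same count tables.  A 20-deep binary history has 2²⁰ states and
cannot be estimated inside one 1000-sample window, so the matrix
builder pools word counts across all windows of a session (without
counting transitions across window boundaries); forcing per-window
estimation at deep histories requires `allow_undersampled`.  An
optional bias correction subtracts the mean TE of 20 seeded
source-shuffled surrogates and clips at zero.

The 6×6 TE matrix uses the sensor order (child, clinician) ×
(left wrist, right wrist, torso), entry (i, j) = TE from sensor j to
sensor i, self-entries fixed at 0 by convention (within-body
cross-sensor terms are computed).  The EMD matrix compares
probability-normalized MMS amplitude histograms on 32 equal [0, 1]
bins; for histograms on a shared ordered grid the optimal transport
cost is the L1 distance between CDFs times the bin width (tested
against a linear-programming transport oracle to 1e-9), and the
distance unit is one bin.  Whole-session histograms are the default;
a frame-averaged mode exists for evolving-similarity displays.

## Screener

Windows are the training unit, subjects the cross-validation unit.
Within each sex stratum, every subject is held out in turn (all their
windows, and all their visits — folds are grouped by subject), an
RBF-kernel SVM (C = 1, gamma = "scale", balanced class weights, fixed
seed) is trained on the remaining subjects' windows after median
imputation and z-scoring with training-fold statistics only, and the
held-out subject's positive rate — the fraction of their windows
labelled positive — is the screening score.  Balanced class weights
matter because realistic strata are imbalanced (e.g. 4 NT vs. 12 ASD
males); without them the positive rates saturate and lose ranking
resolution.  ROC curves sweep the unique scores as thresholds
(score ≥ threshold positive) anchored at (0,0) and (1,1); the
trapezoidal AUC equals the Mann–Whitney pair-counting statistic with
ties worth one half, and is tested against that oracle.  The subject
decision threshold (default 0.5) does not affect the AUC.

## Synthetic dyad generator

Each sensor's speed is a smooth slow baseline (two incommensurate
sinusoids, ±8% of the agent's baseline amplitude) plus raised-cosine
bursts of 31 samples whose peak amplitudes are Gamma(k, θ) draws
scaled by the baseline amplitude.  Spiking is a renewal process with
Gamma-distributed intervals; a coefficient-of-variation knob spans
clock-like (CV → 0) to Poisson-like (CV = 1) spiking.  The minimum
inter-spike spacing is 15 samples (about half the bump width) so that
consecutive bursts remain resolvable as distinct speed peaks; even
so, exponential gap tails merge a fraction of bumps, which is the
dominant source of pipeline-versus-ground-truth disagreement.
Triaxial channels are a smoothly varying random unit direction times
the target speed, so their Euclidean norm reproduces the speed
exactly and the direction is irrelevant downstream.

Defaults describe the recording conditions the pipeline targets:
128 Hz, six sensors, 3300-s sessions (tests and the acceptance script
pass shorter durations, stated below), 2 bursts/s, child amplitude
law (k = 2, θ = 0.5) versus a more mature clinician (k = 4,
θ = 0.25), weak clinician-led coupling (0.3 at lag 4 samples) and
moderate child jitter (0.3).

Two knobs encode the scientific contrasts:

* **Noise (`with_child_noise`).**  The MMS normalization is scale-
  invariant, so a pure change of the Gamma scale is *mathematically
  invisible* downstream; noise changes must move the shape.  The knob
  therefore moves (k, θ) along the iso-mean line kθ = const — exactly
  the empirical maturation law (log k linear in log θ with negative
  slope): higher θ comes with a lower, more exponential-like shape.
  Estimated NSR then rises monotonically with the knob.
* **Autonomy (`child_jitter`).**  Gates whether clinician-triggered
  spikes occur (probability `c·(1−jitter)`) *and* sets the CV of the
  child's own renewal spiking.  At 0 the child is clock-like and
  clinician-led (low entropy rate, high clinician→child TE); at 1 the
  child is Poisson-random and uncoupled (high entropy rate, TE at the
  noise floor).  The child's own rate is reduced by the expected
  triggered rate so the total spike rate stays approximately constant
  across the knob, decoupling autonomy from sheer activity level.

What the generator does *not* emulate: biomechanically realistic limb
kinematics, task structure, sensor noise and drift, accelerometer
channels, or non-stationarity beyond slow baseline drift.  Passing
tests therefore demonstrate estimator correctness and the
direction-of-effect logic of the pipeline on controlled point-process
data — not clinical validity on real recordings.

## Problem sizes and numerical choices

The test suite and acceptance script scale simulations to desk-scale
sizes, chosen as the package's own benchmark conditions: estimator
calibration at n = 10⁴ (Gamma recovery, ApEn) and n = 10⁵ (TE closed
forms); CI coverage over 500 replicates at n = 10³; knob-monotonicity
sweeps over 20 seeds of 120-s sessions; screener checks over cohorts
of 11 NT + 15 ASD subjects with 150-s sessions (19 windows each),
averaging AUC over 8 cohorts.  End-to-end amplitude recovery compares
the full pipeline fit against an MLE on the generator's ground-truth
normalized amplitudes, as a mean over ten seeded 600-s sessions
(single-session errors range ~1–23%, driven by bump merging).

Numerical conventions: 0-based sample indexing, half-open windows,
timestamps authoritative with uniformity checked to 1e-6 s on read;
log base 2 throughout (entropy in bits, control in log₂ units);
estimator identities asserted at 1e-9; CSV round trips are bit-exact
(`%.17g` on write, round-trip float parsing on read).  Sessions with
unequal stream lengths are truncated to the common overlapping
interval, never padded, because every pairwise metric needs
synchronous samples; clock drift between sensors is assumed absent
(hardware-synchronous acquisition).

## Known limitations

* Plug-in TE at deep histories is biased upward on short data; the
  pooling policy controls but does not eliminate this.  Estimates are
  comparable within a configuration, not across history lengths.
* ApEn of sparse binary trains is dominated by the spike rate; the
  regularity signal is second-order.  The capped template length
  (10 ≪ typical inter-spike intervals) limits sensitivity to
  long-range structure.
* The Fisher CIs are asymptotic; at the 30-sample fit floor they are
  approximate and the bootstrap alternative is preferable.
* The embedding-delay rule inherits the bin-aliasing caveat above on
  noiseless periodic inputs.
* Screener AUCs on synthetic cohorts characterize the pipeline's
  sensitivity to programmed effects, not expected performance on any
  clinical population.
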