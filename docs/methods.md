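# Methods

This note documents the models implemented in `behaviorcp`, the
synthetic-data generator that serves as their test bed, the numerical
choices made where the design was genuinely open, and what passing the
test suite does and does not establish about real data.

## Task model

The task is duration categorization (temporal bisection): a self-initiated
trial presents two brief tones (150 ms, 7 kHz) separated by an interval
drawn uniformly from

I = {0.6, 1.05, 1.26, 1.38, 1.62, 1.74, 1.95, 2.4} s,

symmetric around the 1.5 s categorical boundary.  Long intervals are
rewarded at one choice port, short at the other; errors trigger an 11 s
timeout.  Responses before interval offset are *premature*: punished,
never rewarded, and the interrupted stimulus repeats on the next trial.
`TaskConfig` validates the mirror symmetry of any custom stimulus set and
holds the timing constants; video is 120 frames/s for rats and 90 for
mice (`frame_rate`).

Time conventions used throughout: interval onset = trial initiation =
t = 0; windows are half-open [t0, t1); frame k covers [k/fps, (k+1)/fps).
A 1 s window at 120 frames/s therefore has exactly 120 samples, and all
trajectory-vector analyses resample to this common 120 samples/s grid
(mouse data by linear interpolation) before windowing.

## Synthetic sessions

No public dataset accompanies this kind of experiment at the trial level,
so the generator is a first-class, tested component.  Per session, with
trial index t:

* latent bias: z_t = φ·z_{t−1} + ε_t, ε_t ~ N(0, σ_z²), an AR(1) across
  trials (φ = 0.9, σ_z = 0.3; stationary SD ≈ 0.70).  The slow drift is a
  modeling choice — the temporal statistics of such a bias are not
  identified by the analyses here — but some temporally extended latent
  state is required for trajectory-choice coupling to be meaningful.
* choice: P(long) = logistic(β·(ln I_t − ln 1.5) + b + z_t + h·R_{t−1}),
  with sensitivity β = 10 (1/log-s), bias b = 0, and history weight
  h = 0.5 on the signed previous reward R_{t−1} (+1 reward after long,
  0 no reward, −1 reward after short).  These defaults put accuracy near
  99% on the easiest stimuli and ~68% on the hardest — the well-trained
  regime in which psychometric curves asymptote at 0 and 1 — while
  leaving the latent-bias and history effects large enough to be
  detectable at session scale.
* premature responses: probability (stimulus/boundary)·r with base rate
  r = 0.067, so longer waits are harder to withhold and the average rate
  over the (boundary-symmetric) stimulus set equals the base rate typical
  of trained rats.  Premature stimuli repeat on the next trial.
* trajectory (one row per trial, on [−0.5, 2.5) s):

  position_t(·) = template(·) + g·z_t·mode(·) + smooth noise + jitter.

  The *template* is the subject's idiosyncratic behavioral sequence:
  cosine harmonics of the 3 s analysis window with hash-seeded amplitudes
  and phases (SD 50 px), drawn from disjoint frequency slots per subject
  so that templates of different subjects are near-orthogonal — the
  within-/cross-subject correlation structure is then built in rather
  than left to chance.  Subjects also sit at distinct baseline positions
  (60 px spacing): with a shared port geometry, the dominant pooled
  principal component of trajectories is the common spatial axis, which
  matters for the GLM analysis below.

  The *mode* is a fixed unit-norm half-cosine ramp rising from t = −0.5 s
  to a plateau at t = +0.5 s: the latent bias is expressed as a sustained
  lean along the port axis, with the same sign for every subject (toward
  the long port), already present before interval onset.  The gain
  g = 300 px per latent unit gives sustained choice-related separations
  of order ten pixels — the magnitude visible in choice-split average
  video.  g = 0 decouples trajectories from choice entirely, giving an
  exact null for calibration tests.

  Trial-to-trial motion noise is *smooth*: a Gaussian process obtained by
  convolving white noise with a 0.15 s Gaussian kernel (SD 10 px),
  plus 1 px white measurement jitter.  Smoothness is essential, not
  cosmetic: real body motion is temporally correlated and hence
  effectively low-dimensional within a 1 s window.  With white
  per-sample noise instead, 120-dimensional class-conditional density
  estimates have enough spurious degrees of freedom that in-sample Bayes
  posteriors memorize the training labels, a pathology smooth real
  trajectories do not permit.

What the generator does **not** emulate: reaction-time structure and the
actual premature-response truncation of trajectories (premature trials
get full-length trajectories here and are simply excluded by the
analyses); any 2-D or out-of-plane motion (trajectories are generated
directly in port-axis coordinates; 2-D geometry exists only in the frame
renderer); non-stationarities across sessions beyond the AR(1) bias; and
subjects whose heads barely move.  Passing tests on this generator shows
the estimators are correct and calibrated under the assumed structure —
not that real trajectories carry choice information.

## Head tracking

Background = per-pixel median over frames (robust while the animal
transits any pixel in a minority of frames; mean available).  Animal =
largest connected component of |frame − background| > threshold
(default 25 intensity units, minimum area 20 px).  The principal axis
comes from the mask's second-order central moments; candidate head tips
are sub-pixel centroids of the mask pixels within 1 px of the extreme
projections along that axis.  The tip is disambiguated by proximity to
the previous frame's head (the first frame takes a caller hint) or, in
fixtures rendered with a bright head marker, by local intensity.  A
near-isotropic mask (axis ratio < 1.2) is flagged degenerate.  Missing
detections are linearly interpolated up to 5 consecutive frames; longer
gaps flag the trial unusable.  Analysis uses only the projection of the
tip onto the unit port-axis vector; orthogonal motion is discarded.

## Psychometrics

Maximum-likelihood logistic regression of choice = long on log duration
(the stimulus set is near-geometric; a linear-duration predictor is
available since the appropriate scale is not identified a priori).  No
lapse parameter: well-trained subjects' curves asymptote at 0 and 1, and
a plain logistic keeps the bias point interpretable as
exp(−intercept/slope).  Complete separation is flagged
(`converged_ = False`) rather than penalized.  Subject summaries average
intercept and slope over converged session fits; session screening by
easiest-stimulus accuracy is available as a configurable filter only.

## Trajectory similarity

Pearson correlations between all trial pairs, by default on trials of
the longest interval (behavior can unfold longest before the offset tone)
over the window [0, 2.4) s.  Trajectories are not z-scored first —
Pearson is location/scale invariant per pair.  Flat (zero-variance)
trajectories yield undefined coefficients, excluded from partitions with
a count.  Group distributions (same session / same subject, different
session / different subject) are compared with two-sample KS tests
(asymptotic p-values).

## Instantaneous choice probability

At each timepoint, CP = max(A, 1−A) where A is the auROC between head
positions on long- and short-choice trials, computed by the rank-sum
identity with average ranks, so ties count one half and the estimator
equals exhaustive pair counting exactly.  The null band is one-sided, as
a 95% interval around chance: the 95th percentile of the rectified
statistic over 100 random label permutations, per timepoint.  Because
ranks do not depend on labels, all shuffles reduce to one matrix product
over the pre-ranked data, making the 100-shuffle null essentially free.
The analysis is applied separately per subject and stimulus; the
provided selector pools each subject's sessions at the stimulus whose
summed choice variance is highest.

Rectification makes CP ≥ 0.5 by construction, so the null band too is
computed on rectified shuffles; calibration of the resulting
95th-percentile rule is verified empirically (false-positive rate 5% ± 2%
over 500 null sessions).

## Trajectory choice probability

Trajectory vectors **H** are the 1 s window centered on interval onset
(120-D).  Class-conditional densities P(**H** | C) are Gaussian mixtures
(2 components per class, full covariances, ridge 1e−6 on diagonals) fit
by weighted EM: each trial's weight is the binomial choice variance
n·p̂(1−p̂) of its (session, stimulus) cell, entering as a multiplicity in
responsibilities and sufficient statistics (weights are normalized to
mean 1 per class; the MLE is invariant to that scale).  The weighting
concentrates the fit on ambiguous stimuli, where choice variability is
not already explained by the stimulus; unanimous cells get weight 0 and
provably no influence.  Class priors P(C) use the same weights.  Flat
(uniform) weights are available as a robustness option.

Posteriors P(C | **H**) = P(**H** | C) P(C) / Σ_C' P(**H** | C') P(C')
are computed in the log domain (never NaN, invariant to any common
rescaling of the likelihoods).

Dimensionality guard: full-covariance density estimation needs tens of
effective samples per dimension.  When a class's Kish effective sample
size falls below 30 · (components) · (dimensions), the model is fit in
the top-k PCA subspace retaining ≥ 90% of pooled variance, with a logged
warning.  At realistic session sizes (thousands of trials against 120
dimensions) the guard is active; without it, in-sample posteriors
degenerate into label memorization and per-bin psychometrics become
choice-conditioned rather than bias-conditioned.

Trials are grouped into 6 equal-count CP bins (stable sort, counts
differing by at most 1, ties broken by trial order) and a psychometric
function is fitted per bin.  Bins indexed by increasing P(long | **H**)
have *decreasing* bias points — more long-biased pre-stimulus behavior
means shorter durations are judged long — so the ordering statistic
reported by the tests is a Spearman correlation of −1 between bin index
and bias point.

## Choice GLM ladder

Design construction drops premature trials, their immediate successors,
and each session's first trial (no history).  Subjects are indicator
coded (first level absorbed by the intercept); interval enters in linear
seconds (distinct from the psychometric module's default — the model
table convention lists bare I; configurable); trajectory features are
the first two principal-component scores of a PCA pooled over all
subjects' windowed trajectories; history terms are R_{t−1},
d(I_{t−1}) = |I_{t−1} − 1.5|, and I_{t−1}.  Models 1–4 nest by
construction on their initial specifications.

Fits are maximum-likelihood logistic regressions; deviance = −2·loglik,
AIC = deviance + 2k, BIC = deviance + k·ln n computed from these
identities directly.  Prediction success is the percentage of trials
whose fitted P(long) ≥ 0.5 matches the choice (ties predicted long),
in-sample.  Perfect separation is flagged and refit with a tiny L1
penalty.  Likelihood-ratio tests use the deviance difference against a
χ² with df = parameter-count difference, for pairs declared nested on
initial specifications.

Stepwise refinement is greedy best-first on BIC: at each step all
single-term removals (respecting hierarchy — a main effect stays while
any of its interactions is present) and all pairwise interactions among
current main effects are scored, the best accepted, stopping at a local
minimum.  The search is deterministic given the data.

## Pipeline

`behavior-cp run` executes simulate → (optional tracking) →
psychometrics → similarity → instantaneous CP → trajectory CP → GLM.
Per-stage seeds derive from the master seed by stable (BLAKE2) hashing,
so stages can be re-run independently; every output carries the
configuration hash and seed, and reruns with the same configuration are
byte-identical (wall-clock timings go to `run.log` only).

## Problem sizes used by the test suite

The acceptance-style checks run at deliberately chosen scales: 4,500
trials per session for the CP-binning analysis (20 replicates; the scale
of a subject's pooled sessions), 50 + 50 replicates of ~5,000-trial
three-subject datasets for the model-comparison ladder, 500 null
sessions of 40 trials for shuffle-null calibration, 100 sessions of 450
trials (the typical daily session size) for psychometric recovery, and
120-frame rendered stacks for tracking recovery.  These sizes give the
property checks comfortable statistical margins while keeping the whole
suite around a minute of compute.

## Known limitations

* The generator's latent bias is AR(1) by assumption; none of the
  analyses identify its true temporal structure.
* Premature trials carry full synthetic trajectories (real premature
  responses truncate the trial); analyses exclude them, so only the
  repetition rule and exclusion logic are exercised.
* The trajectory CP model assumes Gaussian-mixture class densities on a
  linear subspace; heavy-tailed or strongly nonlinear trajectory
  variability would call for different density models.
* Prediction success is in-sample, as is the CP binning; held-out
  variants exist (`test_well_separated_classes_heldout_accuracy`
  exercises one) but are not the default reporting path.
* Tracking assumes a single animal, a static background, and in-plane
  motion; vertical (out-of-plane) movement is invisible to the port-axis
  projection.
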