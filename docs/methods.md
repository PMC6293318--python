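# Methods

This note documents the models and procedures `moodsig` implements, the
parameters that matter, and the design choices made where the design was
genuinely open. It states nothing the test suite or `scripts/acceptance.py`
does not itself compute.

## From mood reports to paths

A *report* is one timestamped observation of six mood categories (anxiety,
elation, sadness, anger, irritability, energy), each an integer 1–7.
Reports are windowed per participant into *buckets* of exactly L = 20
consecutive observations. Consecutiveness is by observation order, never by
calendar day: missed days and several-reports-per-day both leave the
bucketing unchanged, which is the main practical virtue of the
representation. Non-overlapping windows are the default for classification;
prediction windows slide by one observation to maximise training pairs.

Each bucket becomes a piecewise-linear path on the unit interval with seven
coordinates. Coordinate 1 is normalised time; coordinates 2–7 are, per
channel, the cumulative sum of (score − centre)/6, prepended with an origin
point. Centred increments lie in [−1, 1]; high scores become upward trends
and oscillating scores oscillating paths, and with mean centring the path
returns to zero at its end.

Open choices, and what was decided:

* **Centring.** Per-bucket channel mean by default for classification — it
  makes the representation invariant to a participant's idiosyncratic
  baseline, which is the right default when the question is about dynamics.
  The fixed scale midpoint 4 is used by default for *prediction*, because
  the target lives on the absolute 1–7 scale and mean centring would erase
  the level information the regressor needs. Both modes are available
  everywhere (`NormalisationSpec`).
* **Time coordinate.** Observation index mapped affinely onto [0, 1] by
  default (gap-robust, consistent with the bucketing contract); actual
  timestamps are available, with same-second ties broken by a one-second
  bump and the origin placed one median inter-report gap before the first
  observation.
* **Divisor.** 6, the width of the Likert range. Any positive constant is
  equivalent up to feature scaling; it is fixed for reproducibility.

## The signature engine

The truncated signature of order n over d = 7 letters has
(d^(n+1) − 1)/(d − 1) coefficients, one per word of length ≤ n, stored flat
in graded lexicographic order (the word manifest exported alongside
features documents the layout; the constant empty-word coefficient is
retained, making the order-2 length exactly 57 = 1 + 7 + 49).

Per linear segment the signature is the truncated tensor exponential of the
increment (level k = Δ^⊗k / k!); segments are combined with Chen's identity,
which in graded-lex storage is a sum of Kronecker products of complementary
level blocks. Everything is truncated at order n throughout — no higher
level is ever formed — so a segment costs O(sig_dim²) and a 20-observation
bucket at order 2 is microseconds. Consecutive duplicate points are dropped
(zero increments are signature-neutral). Degenerate inputs: a fully
constant path has the identity signature; paths need ≥ 2 points; non-finite
coordinates are rejected.

Correctness is established by three independent routes, none sharing code
with the engine:

* **Numerical iterated integration** (`brute_force_signature`): the word's
  nested integrals accumulated by the trapezoidal rule on a fine
  subdivision, exact for the empty word and single letters, second-order
  convergent otherwise. At 10⁴ subdivisions per segment the agreement
  asserted is 1e-6 absolute.
* **Exact symbolic integration** (sympy, in the test suite): the same
  nested integrals carried as exact polynomials segment by segment on
  rational paths; agreement asserted at 1e-9.
* **Algebraic identities**: Chen multiplicativity under arbitrary splits,
  reversal inversion, reparameterisation invariance under inserted
  interpolated points, and the shuffle identity
  S(u)·S(v) = Σ_{w ∈ u ⧢ v} S(w), all at 1e-9 (double precision leaves
  orders of magnitude of headroom at these path sizes).

## Classification

`MoodGroupClassifier` is featurizer + random forest. Forest defaults: 500
trees, √p feature subsampling, fixed seed, one job (determinism over
speed). Hyperparameters were not searched; 500 trees is variance-stable at
57 features. Probability-argmax ties are broken in the fixed label order
healthy < bipolar < borderline.

Baselines: per-category mean scores (level information only, no order), and
k = 57 random degree-≤2 monomials of the raw flattened stream (normalised
time plus six raw channels × 20 observations = 140 coordinates; the full
degree-≤2 basis would need 140 + 140·141/2 = 10 010 features). The
quadratic construction — uniform coordinate choices, degree 1 or 2, random
sign, drawn reproducibly from a seed — is one reasonable reading of
"random quadratic functionals" and is pluggable.

Evaluation: overall accuracy, one-vs-rest sensitivity/specificity/PPV,
pairwise binary accuracy and ROC AUC for the three group pairs (AUC equals
the normalised Mann–Whitney U of the model scores; asserted on fixtures),
and bootstrap mean ± sd of accuracy (training set resampled with
replacement, default 200 reps, test set untouched).

Two split modes exist because they answer different questions: splitting by
*bucket* lets one person's buckets land on both sides and measures
within-study discrimination (this reproduces the original protocol);
splitting by *participant* is the honest generalisation estimate and the
recommended default. On synthetic cohorts with stable participant traits
the by-bucket accuracy is, as expected, at least the by-participant
accuracy; both are reported, and participant-level accuracy is additionally
available as the majority vote of the triangle.

The *triangle*: for each participant, a classifier trained on everyone
else's buckets classifies the held-out person's buckets; the three
proportions (summing to one exactly) place the participant in the
2-simplex, projected to the plane with healthy at (0,0), bipolar at (1,0),
borderline at (½, √3⁄2). Participants with fewer than 5 buckets are
excluded to avoid extreme proportions from tiny counts.

## Prediction

Per clinical group, a multi-output random-forest regressor (default 200
trees; six separate forests available) maps the order-2 signature of a
20-observation window, midpoint-centred, to the six scores at horizon h
observations ahead. Predictions are real-valued, clipped to [1, 7]. A
prediction is *correct* when |ŷ − y| ≤ 1; the raw (unrounded) difference is
used by default since a forest average is fractional, with rounding
available and tested. Note that an integer-valued predictor enjoys a
structural advantage under this rule (its ±1 window always covers three
scores), which is why the naive benchmark — copy the window's last score —
is compared primarily on MAE. Horizons count observations, not days.

## The synthetic cohort generator

The generator emulates the shape of a smartphone mood-monitoring study:
three diagnostic groups (defaults 51 healthy / 48 bipolar / 31 borderline),
near-daily reports over months (median study lengths 276 / 353 / 313 days,
±25% jitter), 81.2% daily compliance, occasional same-day repeat reports
(probability 0.05), timestamps jittered within the day.

Per participant, a latent linear-Gaussian state evolves in discrete daily
time: one or more AR(1) mood factors z_t (persistence `factor_phi`,
innovation `factor_sigma`), which each channel follows with a per-channel
lag in observations — lags are what make cross-channel *order* informative
while leaving every marginal distribution untouched, since the factors are
stationary. On top: per-channel AR(1) idiosyncratic noise, a per-participant
trait offset (sd `participant_sd`), and signed episode shocks (Poisson
starts, geometric duration, amplitude in latent units) shared across
channels. Each *filed report* adds fresh iid reading noise (`obs_sigma`)
before the latent value is thresholded onto 1–7 by fixed symmetric
cut-points (±0.5, ±1.5, ±2.5; latent 0 ↦ score 4, the modal score at
baseline). All randomness flows from one cohort seed through spawned
per-participant substreams; identical spec + seed is byte-identical.

Three purpose-built configurations define the conditions under which the
pipeline's claims are tested:

* **Order-only contrast** (`make_order_only_contrast`): channels form three
  pairs, each driven by its own factor (phi 0.8, sigma 0.75; channel noise
  0.35 AR 0.2; reporting noise 0.4); within a pair one channel leads by one
  observation. Groups differ *only* in which channel of each pair leads
  (healthy: first of each; bipolar: second of each; borderline: mixed).
  Swapping the leader is a covariance-preserving relabelling, so the joint
  distribution of the six bucket means is exactly group-invariant — not
  merely the marginals — and mean-score classification is chance by
  construction (a chi-square check on suitably thinned reports is part of
  the test suite; thinning matters because consecutive reports are
  autocorrelated and a naive chi-square would be anti-conservative even
  under this true null). Only direction-of-time statistics, such as the
  signature's level-2 Lévy areas, separate the groups. Evaluated at 50
  participants/group, 296 days (~240 reports each), participant-level
  split.
* **Predictability gradient** (`make_predictability_gradient`): no shared
  factor; per-channel AR(1) with persistence 0.45 / 0.55 / 0.65 and
  state-innovation sd 0.30 / 0.55 / 0.80 and reporting-noise sd 0.45 /
  0.65 / 0.90 for healthy / bipolar / borderline — predictability
  decreasing, mean reversion decreasing, noise increasing across the
  groups. Reporting noise is deliberately part of the gradient: a
  last-value benchmark pays the reading error twice (in the copied value
  and in the target) while a model that smooths over the window pays it
  once, which is precisely why windowed prediction can clearly beat naive
  copying. Evaluated at 30 participants/group, 150 days.
* **Decay pair** (`make_decay_pair`): a slow, quiet mean-reverting group
  (phi 0.93, innovation 0.55, reporting noise 0.2 — a state the windowed
  model can track well, so horizon-1 accuracy is high and decays by ~6
  points to horizon 5) against a memoryless control (phi 0, sd 1.3) whose
  accuracy is flat in the horizon by construction. Evaluated at 25
  participants/group, 120 days, horizons 1–5, 100-tree regressors.

Problem sizes above were chosen as the package's standard evaluation scale:
large enough that the Monte-Carlo error of an accuracy estimate is ~1–2
percentage points, small enough to iterate on.

What the generator does **not** emulate: clinically validated mood
dynamics, medication effects, circadian/time-of-day structure, informative
missingness (compliance is independent of state), free-text or sensor
channels. Passing tests therefore demonstrate that the pipeline recovers
the statistical structures it targets — order information, predictability
ordering, horizon decay — from data of realistic shape; they do not certify
accuracy figures on any clinical population.

## Numerical conventions

Algebraic signature identities asserted at 1e-9; quadrature oracle at 1e-6
with 10⁴ subdivisions; triangle proportions sum to 1 within 1e-12; all
model seeds fixed and threaded explicitly; forests run single-threaded for
bit-reproducibility. Monte-Carlo slacks in the synthetic-recovery tests
(±5 points around chance, 1.5-point monotonicity slack, 5-point flatness
band) were fixed from the expected binomial error at the stated sample
sizes before the assertions were run.

## Known limitations

* Order-2 signatures of mean-centred paths discard absolute level by
  design; classification of groups that differ mainly in level should use
  the mean baseline or midpoint centring.
* The signature features summarise a window with polynomial-in-time
  weightings; they cannot reproduce the exact last observation, so for
  extremely persistent, low-noise processes the naive benchmark is a
  genuinely strong competitor.
* The random-quadratic baseline is one construction among many the phrase
  admits; conclusions about it are specific to the documented generator.
* Bootstrap resampling is by bucket, not participant, mirroring the
  original protocol; a cluster bootstrap would be the natural extension.
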