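# Methods

## The task model

Both games move a ball from the origin to a target at (0, +24) game
units (GU). Angles are measured between the start→sample chord and the
start→target ray, counterclockwise positive, clockwise negative. A
session is four blocks; Push ball runs 20 baseline, 90 learning
(0.5°/trial ramp to −30° over 60 trials, then 30 hold trials), 20
error-clamp, and 30 washout trials (160 total; trials 111–130 are the
clamp). Launch ball doubles baseline to 40 trials (180 total) because
its point-and-shoot interface is less familiar; all later blocks are
identical. These block lengths are the unique assignment consistent
with the session totals and the clamp's position in the trial sequence.
The first ramp trial already applies −0.5°, so ramp trial 60 reaches
−30° exactly. A displayed final angle within ±10° of the target center
is a hit, boundary inclusive. Clamp trials display only a jitter drawn
uniformly on [−2, 2]° (independent per trial; the distribution of the
small "natural variation" rotation is not otherwise constrained), so
every clamp trial succeeds and the error signal is removed.

## The synthetic participant

No generative model is fit to real data anywhere in this package; the
simulator exists to give the analysis stages a test bed with the
qualitative structure of developmental visuomotor adaptation: gradual
learning, retention with slow decay under the clamp, near-zero clamp
compensation, and young children succeeding through online steering
rather than adaptation. The minimal mechanism with these signatures is
a single-rate state-space learner plus proportional within-trial
steering:

* **Trial-to-trial**: the planned direction x (degrees) updates as
  `x[n+1] = A·x[n] − B·e[n]` with retention `A = 0.98` (fixed),
  learning rate `B`, and `e[n]` the displayed angle at the
  initial-angle readout point — i.e. *before* any steering, so feedback
  corrections do not contaminate the teaching signal. On clamp trials
  `e` is the clamp jitter, giving geometric decay at rate A.
  Two-rate and memory-of-errors learners are out of scope.
* **Within-trial**: the plan is x plus Gaussian planning noise. On
  Push-ball non-clamp trials, after a visual-delay fraction (default
  0.25 of the movement extent, reflecting ~150–180 ms visual delays
  against child movement times) the heading relaxes exponentially
  toward the hand angle that zeroes the displayed error; the feedback
  gain `G ∈ [0, 1]` sets the fraction of the remaining error closed by
  movement end. Launch ball and clamp trials provide no usable on-line
  error, so steering is disabled there.
* **Sampling**: positions are emitted at the participant's polling rate
  with ±20% multiplicative inter-sample jitter; the click contributes
  the single origin sample and stationary periods produce no polls.
  Per-sample motor noise is positional: its angular footprint is full
  at the 1.2 GU initial-angle readout distance and decays ~1/distance
  beyond it, so the initial angle carries sd ≈ `motor_sd` while late
  samples wiggle by a roughly constant lateral offset. A Push-ball
  trial ends at the first sample whose displayed position crosses the
  target plane (y ≥ 24 GU).

### Age parameterization

Ages are drawn uniformly over the configured range (36–216 months by
default; adults are flagged at ≥216 months) unless an explicit age list
is supplied. Per participant:

* the end-of-learning adaptation target is
  `clip(a + b/age_mo, 0, 28)` with defaults `a = 25.16°`,
  `b = −720.9°·mo`, plus between-participant jitter (sd 5°); `B` is
  then solved (bisection) so the deterministic learner's mean state
  over the last 10 learning trials equals the target. The 28° cap keeps
  the target reachable for an `A = 0.98` learner;
* the overall-performance (final angle) target follows its own inverse
  law (`29.7°`, `−295.3°·mo`; jitter sd 2.5°), and
  `G = (FA_target − IA_target)/(30 − IA_target)` — young simulated
  children fill the success gap by steering;
* planning/motor noise and reaction/stationary/movement times decay
  exponentially with age (e.g. plan sd 12° → 3°, movement time
  2.5 s → 0.8 s from age 36 months to adulthood), anchored to the
  magnitudes of the developmental timing differences the task shows
  (IA readout at ~445 ms in 3–4-year-olds vs ~115 ms in adults);
  polling is uniform on 40–90 Hz; the device mix is 60/25/15
  mouse/trackpad/touchscreen and is metadata only (no device-specific
  biomechanics are modeled). The between-participant jitter scales are
  the package's choice of "realistic": they reproduce substantial
  individual scatter while leaving the inverse-age signal recoverable
  at a few hundred participants; observed cohorts are noisier still
  (device, handedness, attention), so real-data fits will have lower
  R² than simulated ones.

Each participant's generator derives from (cohort seed, participant
index), so cohorts are reproducible and order-independent; serialized
cohorts are byte-identical across reruns.

### What the generator does not emulate

Explicit aiming strategies, use-dependent biases, fatigue/attention
drift, device-specific kinematics, screen-refresh aliasing, and
longitudinal (within-child) structure. Passing pipeline tests on this
cohort therefore certifies the *analysis machinery* — measure
definitions, epoch bookkeeping, fitting, and centile estimation — not
behavioral claims about real children.

## Kinematic measures

The movement angle of a sample uses the start→sample chord (not
instantaneous velocity). The initial angle is read at the first sample
whose *Euclidean* distance from start reaches 1.2 GU (5% of target
distance); an along-path variant is available via
`distance_mode="arclength"`. The correction scan starts strictly after
the IA sample, so the IA sample cannot be its own correction point;
normalized correction time divides by movement time (onset = first
sample with nonzero displacement after the click; no velocity
threshold is applied, since raw polled positions are analyzed without
smoothing). IA time is referenced to movement onset. Trials that never
reach the IA threshold or end at the origin are flagged invalid,
excluded from epoch means with the trial count decremented (no
imputation), and counted in the QC log. Launch-ball measure tables
leave normalized correction time blank by design: with no on-line
feedback there is no correction to time.

## Epochs and developmental fits

Epoch windows: last 10 baseline, last 10 learning ("end learning"),
first 3 / last 3 clamp, first 3 washout, last 10 washout. SDs use the
n−1 denominator. Age enters all fits in months (years × 12). Adults
(≥216 mo) are excluded from every developmental fit and from centile
estimation but retained in group summaries. The inverse and logarithmic
models are OLS on the transformed predictor; the exponential model is
nonlinear least squares with a deterministic start (a₀ = y at the
youngest age, b₀ from a log-linear regression of |y| on age). All CIs
are 95% Wald intervals (profile-likelihood intervals would differ
slightly for the exponential fit). Model selection takes the highest
adjusted R², with exact ties resolved toward the inverse model, whose
plateau form is the biologically motivated default.

## LMS reference curves

Families implemented: NO and BCCG. BCT and BCPE (kurtosis-modeling) are
out of scope; when BCCG diagnostics leave significant kurtosis
z-scores, the residual-moment table is the intended evidence. Each of
λ, μ, σ is a cubic regression spline in age — df = 0 is a constant,
df 1–2 polynomial, df ≥ 3 a B-spline with df − 3 equally spaced
interior knots (bases nest through df 0–4). Defaults: df 3 for μ and σ,
df 1 for λ (kept stiff; λ is weakly identified at cohort sizes of a few
hundred). μ and σ use log links under BCCG (identity/log under NO), and
coefficients maximize the exact log-likelihood via L-BFGS-B from a
deterministic start (λ₀ = 1, μ₀ from a least-squares smooth of y or
log y, σ₀ from residual spread), so fits are seed-free. AIC is
−2 log L + 2·(number of free coefficients); NO's fixed λ ≡ 1
contributes zero df. The BCCG density omits the positive-support
truncation term, which is negligible for σ ≪ 1/|λ| (standard LMS
practice). Quantile residuals use nine *equal-count* age groups (the
precise data-driven grouping rule used in centile practice varies and
is not standardized here); moment z-scores use the large-sample
standard errors √(1/n), √(2/n), √(6/n), √(24/n).

A note on estimator precision: λ's information enters through the
sample skewness, so sd(λ̂) ≈ √(6/n)/(3σ) — about 0.12 at n = 2,000 and
σ = 0.15. Single-dataset λ estimates at that size scatter accordingly;
recovery claims in the tests therefore average over replicates.

Outliers are excluded only via an explicit user-supplied list
(`--exclude`); there is no automatic rejection. Sex-stratified curves
should pick the family on pooled data and refit per stratum with that
family; the `centiles` CLI supports this by running the pooled
selection first and then passing `--family` per stratum.

## Pipeline, formats, QC

Sessions are JSONL, one record per trial (schema in `reachdev.io`),
chosen over per-participant files for streamability; `.gz` is handled
transparently. Numeric fields are written with ≤6 fractional digits so
write→read→write is byte-stable. QC excludes participants for sessions
over 120 minutes, median movement-phase polling under 20 Hz, or
incomplete sessions; every exclusion is logged with its rule, and the
structured per-stage logs (counts in/out) are the pipeline's audit
trail. The `run` pipeline threads a single seed through every stage;
no stage reads the wall clock for computation, so artifacts are
byte-reproducible.

## Problem sizes used by the test suite

The suite favors sizes that exercise the estimators' operating range:
500 random fixtures for oracle equivalence; 1,000 simulated clamp
phases for the retention check; a 200-participant default cohort for
end-to-end parameter recovery; 50 replicates of n = 2,000 for BCCG
recovery; the shared module-test cohort is 80 participants. These are
the package's reference experiment sizes; larger cohorts only tighten
the same checks.

## Known limitations

* The state-space learner is deliberately minimal; it cannot express
  savings, explicit strategy, or differential learning/forgetting
  rates, and simulated washout is symmetric with learning.
* Wald CIs for the exponential and LMS fits understate uncertainty in
  small samples.
* BCCG cannot model kurtosis; heavy-tailed measures will show it in
  the residual-moment table rather than being absorbed by the fit.
* The clamp's 20-trial placement at trials 111–130 is one of two
  readings of a 21-index description of the clamp window; the schedule
  builder pins the 20-trial version.
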