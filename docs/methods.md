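# Methods

`smartrar` simulates two-stage sequential multiple assignment randomized
trials (SMARTs) under response-adaptive randomization (RAR) driven by
Thompson sampling, and estimates the values of the trial's embedded
regimes with inverse-probability-weighted estimators whose
variance-stabilizing weights keep normal-theory inference valid under
adaptation.  This note records the models, the tunable parameters and
their defaults, the numerical conventions, and what the synthetic
scenario does and does not establish.

## Trial model

Time is integer weeks.  A subject enrolled at week `tau` is assigned
stage-1 treatment at `tau`, has interim data ascertained and stage-2
treatment assigned at `tau + gap`, and has the outcome recorded at
`tau + 2*gap`, with `gap = 6` weeks by default.  Data observed at week
`t` become usable for the policy update at week `t + 1` (the strict
past), and every subject randomized in the same week and feasible group
shares one probability vector.  All subjects complete: dropout, missed
visits, and non-integer accrual are out of scope.  The update cadence is
a configurable integer period; only weekly updates are validated.

Two randomization schemes are implemented.  *Up-front* randomization
assigns each subject a whole embedded regime at enrollment; the regime's
stage-2 rule is then applied mechanically to the realized response.
*Sequential* randomization assigns one treatment per stage, with stage-2
probabilities specific to the four (initial treatment, response) groups.
Uniform ("simple") randomization is the up-front scheme with a fixed
uniform vector and unit weights.

Every ledger record stores the exact probability vectors (and
stabilizing-weight values) in force at the subject's own assignment
weeks.  All propensities used downstream are read back from these stored
values, which makes post-trial estimation independent of the policy code
and lets a completed-trial CSV be analyzed on its own.

## Thompson sampling via confidence distributions

At week `t` the belief that option `j` is optimal is the fraction of `B`
draws from an estimated confidence distribution in which `j` attains the
optimum (ties split equally, so beliefs sum to one exactly).
Randomization probabilities are `rho^c_t` normalized, then clipped to
`[0.05, 0.95]` and renormalized once — a single clip-and-normalize pass,
so an entry can end slightly below the floor after renormalization;
strict positivity always holds and stored propensities use the final
vector.  The damping constant `c_t in [0, 1]` interpolates between
uniform randomization (0) and full probability matching (1); constant
schedules are validated, increasing schedules are supported but not
checked against any reference numbers.

*Up-front:* the confidence distribution is the multivariate normal at
the current value estimates with the stacked M-estimation sandwich
covariance (weights treated as fixed, so no weight-estimation
uncertainty is propagated); `B = 1000` draws per update.

*Sequential:* Q-learning with linear models.  The stage-2 fit is
ordinary least squares of the outcome on
`(1, x1, I(a1=1), x21, I(a2=1), I(a2 in {2,5}), I(a2=3), I(a2=4))`,
with coefficient covariance `sigma^2 (Phi'Phi)^{-1}` and residual
variance computed with denominator `n` (no degrees-of-freedom
correction).  The stage-1 estimator regresses the per-subject optimized
stage-2 model value on `(1, x1, a1)` and is a nonregular function of the
stage-2 fit, so its confidence distribution is sampled projection-style:
32 outer stage-2 draws, a stage-1 refit per outer draw, 32 inner draws
from each conditional normal, pooled into 1024 stage-1 draws (stage-2
beliefs use 1000 direct draws).  Per-subject beliefs are the fraction of
draws in which an option optimizes the fitted model at that subject's
history; under the feature sets above the argmax depends on the history
only through the feasible group, so beliefs are evaluated once per group.
Histories with a single feasible option carry the observed outcome back
as the pseudo outcome.

*Burn-in:* probabilities stay uniform until every embedded regime has at
least 25 completers whose realized treatments are consistent with it
(the default; configurable).  The week this first holds is `t*`;
adaptation and weight updates begin at `t* + 1`.

## Value estimators and stabilizing weights

For regime `j`, a subject's stage propensities are the probabilities of
the regime-recommended actions under the policy in force at the
subject's own assignment weeks (for the up-front scheme these are sums
of the stored regime probabilities; for the sequential scheme the stored
per-option probabilities).  The weighted IPW estimator is the ratio of
weighted consistent-completer outcomes to weighted consistent-completer
indicators, each inverse-propensity weighted; the weighted AIPW
estimator normalizes by the weight total and adds a telescoping
augmentation built from partial-consistency indicators and fitted
conditional-mean models `L_k`.  Unit weights recover the unweighted
IPW/AIPW estimators bit-for-bit.

Augmentation models follow the backward-iterative recursion: a shared
stage-2 outcome regression, regime-specific pseudo outcomes at the
regime's recommended action, and a regime-specific stage-1 regression on
`(1, x1, a1, x1*a1)`.  For a subject enrolled at week `tau` the models
are fitted only on data observable strictly before `tau` (required for
conditional unbiasedness under adaptation); fits are computed once per
enrollment week and cached.  Weeks with fewer completers than the
feature dimension fall back to `L = 0`.  Near-singular normal equations
get a ridge of 1e-8; estimated variances are floored at 1e-12.

Under adaptive randomization the observed data are not i.i.d. and the
unweighted estimators need not be asymptotically normal.  The
stabilizing weights hold the conditional second moment of the
estimating-function terms constant over weeks: response-stratum moments
`mu^{(s)}` are estimated by inverse-propensity-weighted squared
residuals around the snapshot's unweighted IPW estimate, reassembled
with the *current* week's probabilities into `Xi_t`, anchored at the end
of burn-in, and applied as `W_t = sqrt(Xi_{t*} / Xi_t)` (weights are 1
through burn-in).  When a stratum has no consistent completer or `Xi`
is nonpositive, the previous weight is held; a regime's anchor is set at
the first week where both strata are populated.

The corresponding weights for the augmented estimator are this package's
own construction (the reference construction is not published): the
conditional second moment of the augmented integrand is decomposed into
policy-free components — `E[(L1 - theta)^2]`, the regime-arm term
`E[(L2 - L1)^2]`, and stratum terms `E[I(s)(Y - L2)^2]` — each estimated
by inverse propensity weighting and reassembled with current-week
probabilities; anchoring and the square-root-ratio form are unchanged.
The sequential scheme uses realized per-subject product propensities in
the moment estimates and current-policy group probabilities in the
reassembly.  These analogs are validated through the martingale
properties they are designed to deliver (conditional unbiasedness, flat
conditional second moments, near-normal standardized estimates), not
against any external formula.

Inference uses the martingale CLT form: the standard error is
`sqrt(sum M_i^2) / |sum dM_i|` with `M_i` the estimating-function terms
at the estimate, which equals `sigma_T / (|delta_T| sqrt(T))` in
estimating-equation notation; two-sided intervals and one-sided bounds
are normal quantiles.  Cross-regime covariance comes from per-subject
outer products of the stacked terms; regimes on different stage-1 arms
share no subjects and are exactly uncorrelated under the IPW estimators.

## The synthetic scenario

The bundled generative model emulates a behavioral cancer-pain SMART:
baseline pain score `X1 ~ N(5, 1)`; interim score
`X21 = 0.9*X1 - 1.5*A1 + e1`; response `X22 = I(X21 < m*X1)`; outcome
`Y = offset + 0.3*X1 - 0.75*A1 + 0.6*X21 + effects(A2) + e2` with unit
Gaussian noise at both stages and lower outcomes favorable.  Stage-2
effect codes: maintenance after the brief program -0.25, the full
program or its augmented variant -0.75, stopping after the full program
-0.75, maintenance after the full program -0.85.

Two presets ship.  `as_printed` uses threshold multiplier `m = 0.7`,
under which the brief-program response rate is about 0.163.
`calibrated` — the preset used everywhere results are compared with the
reference value vector — sets `m = 0.9` (equal to the interim-score
slope, making response equivalent to `e1 < 1.5*A1`, with rates 0.5 and
0.9332) and shifts the outcome by -4.201.  These two choices are solved,
not assumed: the value contrast between regimes 4 and 1 isolates
`p_resp(0) * (-0.25)`, the contrast between regimes 5 and 6 isolates
`(1 - p_resp(1)) * (-0.10)`, and the offset follows from regime 6's
value.  The calibration is exposed as an operation
(`calibrate_scenario`) that errors when no single offset fits both
stage-1 arms.  With it, all eight closed-form regime values match the
reference vector within ±0.002 (regime 2, at -0.376 versus -0.374, is
the extreme case), regime 8 is optimal, and regimes 7/8 and 5/6 differ
by under 0.01.

Default study conditions: `N = 1000` subjects with enrollment weeks
independently uniform on 1..24, 6-week stage gaps, weekly updates,
clipping 0.05/0.95, burn-in 25 consistent completers per regime.

### What the scenario geometry implies

With a 24-week accrual window and a 12-week treatment path, the first
completer is usable at week 14 and the 25-per-regime burn-in completes
around week 16–17, so at most roughly one third of subjects can be
enrolled under adapted probabilities, and clipping caps the adapted
optimal-arm probability at about 0.85 (up-front, eight regimes) or 0.95
(sequential).  The in-trial benefit of adaptation achievable under these
conditions is therefore bounded — measured optimal-arm proportions are
about 0.61 (up-front, WIPW-driven, `c_t = 1`) and 0.64 (sequential),
and the sequential optimal-regime consistency is about 0.40 — well below
the rates reported for this scenario in the reference study, which are
only reachable if most enrollment occurs after burn-in (i.e., an accrual
horizon long relative to the treatment path).  The acceptance tests for
those in-trial rates assert the reference values and are expected to
fail under the conditions above; they are retained deliberately rather
than re-tuned.

A second geometry effect: more than half of subjects enroll before any
completer exists, so their strict-past augmentation models are `L = 0`
and they enter the augmented estimators as unnormalized
Horvitz–Thompson terms.  Under these conditions AIPW/WAIPW remain
unbiased with valid (if slightly anti-conservative) coverage, but are
*less* efficient than the ratio-form IPW — the reverse of the ordering
seen when augmentation models are available for most subjects.

### What passing tests do and do not show

The generator is linear-Gaussian with a deterministic visit schedule,
no dropout, no covariate drift, and a response rule driven by the same
noise as the interim score.  Tests passing under it validate the
engine's bookkeeping (no information leakage, stored-probability
integrity), the estimators' algebra and martingale properties, and the
reproduction of the reference scenario's operating characteristics under
uniform randomization.  They do not establish performance under model
misspecification, heavy-tailed outcomes, informative dropout, or
non-stationary accrual, and the Q-learning policy's behavior is only
validated for correctly specified linear models.

## Problem sizes

Monte Carlo sizes were chosen to keep the full test suite and the
acceptance script each under a few minutes of single-core time while
leaving Monte Carlo standard errors small relative to every tolerance
checked: 1000 replications for uniform-randomization operating
characteristics (coverage, MSE, design-forced proportions), 200
replications per adaptive method for in-trial rates, 1000 adaptive
trials for the skewness check of standardized estimates.  The published
tables use 5000 replications; all comparisons here carry Monte Carlo
standard errors and tolerances that account for the reduced replication.

## Known limitations

* Two-stage designs are concrete; the types admit more stages but the
  engine, scenario, and tests target `K = 2`.
* The interim-data (partial-information) estimator and the
  configuration-maximizing variant of sequential belief construction are
  out of scope, as are binary outcomes and null/near-null scenarios.
* The stabilizing-weight constructions for the augmented and sequential
  cases are principled analogs validated by their delivered properties
  (see above), not reimplementations of a published formula.
* Joint covariance treats stabilizing weights as fixed.
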