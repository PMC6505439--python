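# Methods

## The task

The simulated task is a block-structured two-armed bandit. A session has
600 trials in blocks of 20–60 trials. Within a block each arm pays out
`100 × Beta(α, β)` points, with `(α, β)` drawn per block as an unordered
pair from five fixed parameterizations — (1,3), (2,3), (3,3), (3,2),
(3,1) — whose means span 25–75 points. Two trial types are randomly
intermixed: *rating* trials, on which the subject reports a value belief
(0–100) and a belief confidence (0–1) for an arm, and *choice* trials, on
which the subject picks an arm, reports decision confidence, and then sees
the outcome. Two designs are supported:

* `exp1` — 75% rating trials; a rating trial first reveals an outcome
  from one randomly chosen arm, then that arm is rated.
* `exp2` — 25% rating trials; rating trials reveal no outcome and both
  arms are rated, so the only outcome information comes from choices.

Block lengths are drawn uniformly on {20..60} with the tail constrained so
lengths always partition 600 exactly. All subjects of a cohort share one
block schedule, as in the original task design.

## Agents

Each simulated subject is a learner plus a fixed report/choice layer.
Beliefs reset at block boundaries (the payout distributions change).

**Learning rules.** Three families, all maintaining a per-arm value
estimate `V`, a dispersion `s`, and an observation count `n`:

* *ideal* — `V` is the running mean and `s` the running sample SD of the
  outcomes observed for the arm (Welford recursion; `s = 0` for `n < 2`).
* *rl* — delta rule `V ← V + η(r − V)` with
  `s ← (1−η)s + η|r − V_before|`: the dispersion tracks the recent
  absolute prediction error, so surprising outcomes transiently *raise* it
  (and lower reported confidence), a non-Bayesian signature of human
  reports. `s` starts at 25 points.
* *particle* — sequential importance resampling over candidate arm means
  (uniform grid initialization over 0–100). The observation model is a
  beta density with mean equal to the candidate mean and fixed
  concentration ν = 10; systematic resampling (deterministic offset, unit
  Gaussian roughening of candidate means) triggers when the effective
  sample size drops below half the particle count (default 200 particles).
  ν = 10 rather than the true arms' α+β ≈ 4–6 because the
  mean-parametrized beta likelihood has an O(1/ν) bias that pulls its
  single-observation mode toward 50; at ν = 10 the asymptotic bias of the
  posterior under a repeated outcome is under 2 points.

**Confidence readout.** Reported belief confidence is a fixed linear,
clipped map of an *effective dispersion*:

    conf = clip(1 − gain · d_eff / 100 + drift, 0, 1) + report noise

For the ideal and delta-rule trackers
`d_eff = sqrt((n s² + n₀ σ₀²)/(n + n₀))` with prior pseudo-count `n₀ = 2`
and flat-prior SD `σ₀ = 100/√12 ≈ 28.9`: the agent's regularized estimate
of the arm's outcome variability. The particle filter reports its
posterior SD directly. Deliberately, `d_eff` carries no explicit
dependence on the raw observation count beyond the prior wash-out: in
choice-heavy sessions the frequently chosen (higher-mean) arm accumulates
observations faster, and a count-driven confidence readout would convert
that sampling asymmetry into a spurious positive load of the outcome
*mean* on confidence — a load that is small in human reports. Confidence
still rises over a block (the prior term shrinks) and drops after
surprises (via `s` for the delta-rule tracker).

**Subjective-confidence wander.** `drift` is a slow per-arm AR(1) process
(stationary SD 0.25 confidence units, autocorrelation 0.85 per trial,
stationary initialization at block start) shared between confidence
reports and the choice policy. Without it, simulated confidence varies
far less than human reports do, with two consequences: the
uncertainty-bonus doses studied below become undetectable against
cohort-level noise, and the rating-derived exploration labels acquire a
confound (low dispersion-driven confidence coincides with value drift
that flips the carried ranking). The wander is orthogonal to value
errors, so it carries genuine report→choice signal while diluting that
confound.

**Value reports.** `value_rating = clip(V + noise, 0, 100)` with noise SD
`rating_noise_sd/(n+1)^{1/4}` — report precision grows slowly with
evidence, independently of the dispersion estimate. The default
`rating_noise_sd = 14` points was calibrated so the simulated
estimation-error drop across block halves matches the magnitude pattern
of the empirical descriptives this package emulates (first-half ≈ 8,
second-half ≈ 6.5 points, paired t ≈ 8 on 8 subjects) while exploration
rates stay near the empirical 13–22%.

**Choice policy.** With `C_high` the (wander-inclusive) confidence of the
currently higher-valued arm and `|ΔV|` the absolute value difference:

    P(choose lower-valued arm) = logistic(−β_temp |ΔV|/100 + φ (1 − C_high))

Ties in value are broken uniformly. `φ` (the uncertainty bonus, default
0.5) makes exploration increase when confidence in the leading option is
low; `β_temp` (default 8) is the inverse temperature.

**Decision confidence.** A linear map of centred inputs, clipped to
[0, 1], with the sign pattern (+V_chosen, −V_unchosen, +C_chosen,
+C_unchosen) and weights (0.6, 0.35, 0.5, 0.25) around a 0.6 baseline,
plus report noise. Reaction times are log-normal with a median of 800 ms
decreasing in decision confidence (slope 0.8 log-ms per confidence unit,
log-SD 0.25), which yields the negative confidence–RT coupling assumed by
the "time heuristic" control regressor.

## Cohorts

`synthetic_experiment.generate_cohort` draws per-subject parameters from
cohort-level (mean, sd) distributions — Gaussian on a log scale for
positive parameters and a logit scale for the learning rate (delta-method
scaling of the sd), so hard bounds are respected. Default heterogeneity:
learning rate 0.3 ± 0.1, confidence gain 2.0 ± 0.3, uncertainty bonus
0.5 ± 0.15, inverse temperature 8 ± 1.5, rating noise 14 ± 3.5,
confidence noise 0.08 ± 0.02. Per-subject seeds derive deterministically
from the master seed; the whole cohort shares one block schedule.

## Preprocessing

* RT exclusion: per subject, choice trials with RT outside mean ± 3 SD
  (two-tailed — both fast lapses and slow, distracted responses); rating
  trials are never excluded; subjects with < 3 choice trials are skipped
  with a warning.
* Within-subject z-scoring uses the population SD (divide by n).
* Carry-forward: each arm's most recent value/confidence rating is
  propagated onto later trials *within the same block only*; both-arm
  rating trials refresh both slots. Ratings reset at block boundaries
  because the payout distributions change there.
* Exploration label: 1 when the chosen arm's carried value rating is
  strictly below the other's; carried ties and missing ratings make the
  trial unusable rather than being coin-flipped.
* Objective accuracy: 1 when the chosen arm's running mean of all
  outcomes observed so far in the block is ≥ the other's (ties count as
  correct); trials before both arms have an observation are unusable.
* Quantile bins (confidence or trial quintiles) are formed within
  subject; heavy ties merge bins with a warning.

## Statistical models

All predictors are z-standardized before fitting (linear outcomes too, so
coefficients are standardized betas); interaction columns are products of
the standardized main effects.

* **Linear mixed models** (decision confidence; belief confidence) are
  fitted by maximum likelihood with statsmodels `MixedLM`. The random
  structure follows a fallback ladder — all slopes → main-effect slopes →
  random intercept → per-subject fits pooled by inverse variance — and
  the result records which rung converged. The convenience wrappers
  default to the random-intercept rung: with 7–8 predictors and
  desk-scale cohorts the full-slope structures rarely converge, and the
  fixed effects of interest are stable across rungs. p-values use the
  normal approximation to the Wald statistic.
* **Logistic mixed models** (exploration) use the ladder's two-stage
  rung directly: per-subject ML logistic fits (subjects with separation
  or non-identified coefficients are dropped) pooled by
  DerSimonian–Laird random-effects meta-analysis. No installed Python
  package fits frequentist random-slope logistic GLMMs; the two-stage
  estimates track `lme4::glmer` fixed effects on synthetic data (test
  suite cross-check, tolerance 0.15).
* The **belief-confidence model** regresses confidence on the running SD
  and mean of the outcomes observed for the rated arm (including a
  same-trial reveal where the design shows one), log trial number, arm,
  the three two-way interactions among the first three, and the
  three-way interaction. Rows with fewer than two past outcomes are
  dropped (the SD is undefined). Per-subject `sigma_past` betas for the
  metacognition link come from the per-subject OLS fits of the same
  standardized design.
* **Estimation-error halves**: per subject, mean |rating − running
  outcome mean| in the first vs second half of each block (middle trial
  to the first half), compared by paired t-test; a zero-variance
  difference is reported as degenerate.
* **Quintile trend ANOVA**: one-way repeated-measures ANOVA on
  within-subject bin means with the Greenhouse–Geisser correction,
  partial eta squared, and a linear polynomial contrast
  (F(1, n−1) = t² of the per-subject contrast scores). Implemented
  in-package to integrate the contrast; the omnibus F/p/η²p agree with
  `pingouin.rm_anova` to numerical precision (test-suite cross-check).
* **Update-size vs confidence-change correlation**: per subject, Pearson
  r between |outcome − previous rating of the arm| and the change in
  belief confidence across consecutive ratings of the same arm within a
  block; subjects with < 5 pairs are skipped.

## Metacognition

Choice trials are recast as detection: the "stimulus" is the objectively
better arm (running outcome means), the response the chosen arm, and
decision confidence is discretized into K = 4 within-subject quantile
bins (configurable; ties reduce K with a warning). Cells are padded with
1/(2K) when any cell is empty. Type-1 d′ and criterion come from the
marginal response rates; meta-d′ is fitted by maximum likelihood
(Nelder–Mead over meta-d′ and the 2(K−1) type-2 criteria, ordered via a
log-offset parameterization) holding the *relative* criterion c/d′ fixed,
i.e. the sensitivity an equal-variance SDT observer would need for its
type-2 ROC to match the observed response-conditional confidence counts.
M-ratio = meta-d′/d′; subjects with d′ ≤ 0 are flagged undefined. This
per-subject MLE replaces hierarchical-Bayesian group estimation, which is
out of scope here; group-level statements therefore rest on per-subject
point estimates. The tracking link is the Pearson correlation between
per-subject `sigma_past` betas and log M-ratio (≥ 5 defined subjects
required).

## Model fitting

The likelihood walks a log in time order with exactly the agents-module
updates: rating rows contribute Gaussian densities of the value rating
(SD = the agent's evidence-dependent report noise, floored at 0.5 points)
and belief confidence (SD = `confidence_noise_sd`) around the noiseless
readouts, evaluated after updating on a same-trial reveal; choice rows
contribute the policy log-probability of the chosen arm, followed by the
update on the revealed outcome. Clipping at the scale bounds is ignored
in the density (a plain Gaussian is used). The confidence wander is
latent and not part of the likelihood; fitted noise parameters absorb it,
so fits to wander-bearing cohorts are quasi-ML. Recovery and
model-identification studies therefore simulate with the wander off —
the standard self-consistent design for such studies.

Free parameters: gain, bonus, inverse temperature, rating noise,
confidence noise (+ learning rate for the delta-rule family); box bounds
as in `model_fitting.PARAM_BOUNDS`; particle count and observation
concentration are fixed. Optimization is multi-start Nelder-Mead (first
start at the family defaults, the rest uniform in the bounds from a
seeded generator; 10 restarts by default, fewer in the desk-scale
studies). BIC = k·ln(n) + 2·NLL with n the number of contributing trials.
`compare` reports the per-subject fit table, summed-BIC ranking and
best-model counts.

## Problem sizes used in the checks

The test suite and `scripts/acceptance.py` run everything at desk scale,
chosen as the smallest sizes at which each property is comfortably
resolved: 8–30 subjects × 600 trials for the regression properties
(30 subjects — the choice-heavy design's empirical cohort size — for the
uncertainty-bonus dose–response, where the 0.5-vs-1.0 contrast is ~0.04
standardized units); 24 subjects × 400 trials with 4 restarts for
learning-rate recovery; 20 replicate cohorts of 2 subjects × 150 trials
with 2 restarts and 50 particles for model identification; 10,000 trials
for the SDT oracle; 1,000 random logs for the preprocessing
cross-validation.

## What the generator does and does not emulate

It emulates: the block/trial structure and payout distributions of both
designs; confidence that rises with learning, tracks realized outcome
variability, dips after surprises, and wanders idiosyncratically; value
reports that sharpen with evidence; uncertainty-biased exploration;
decision confidence built from both options' values and confidences; RTs
negatively coupled to confidence. It does not emulate: motor/attention
dynamics beyond the log-normal RT placeholder, scale-use idiosyncrasies
(anchoring, digit preference), learning-to-learn across blocks, or any
demographic structure. Passing tests show the pipeline recovers what this
generator plants at these problem sizes; they do not certify effect sizes
in human data, where report maps and noise structure are unknown.

## Known limitations

* The logistic "hierarchical" route is two-stage pooling, not a joint
  GLMM; with very few trials per subject its SEs can be optimistic.
* Meta-d′ is per-subject MLE; with < ~100 usable trials the estimates are
  noisy and the padded-cell correction biases M-ratio toward 1.
* The particle filter's mean-parametrized beta likelihood is mildly
  biased toward mid-scale for extreme outcomes (O(1/ν)).
* The three agent families are single canonical members of their classes;
  alternates (e.g. other confidence dynamics) would need new `model_tag`
  entries.
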