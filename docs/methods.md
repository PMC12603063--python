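# Methods

This note documents the models, the estimation and comparison machinery,
the synthetic-data generator, and the design choices made where the design
was genuinely open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Task structure

A session is `n_blocks × block_length` trials (default 4 × 24 = 96). Group
identity (ingroup/outgroup) is balanced exactly within each block (12/12,
permuted); binary outcomes hit the positive rate (default 75%) exactly
within each group at the session level, in permuted order. Exact per-group
balance was chosen over per-trial randomization because the experience with
the two groups is meant to be objectively equalized; configurations where
`positive_rate × per-group trials` is not an integer are rejected rather
than silently rounded. Two payoff frames exist — gain (0 MU endowment,
partner gives 5 or 0) and loss (10 MU endowment, partner takes 5 or 10) —
that end at identical payoffs for each outcome; the frame is metadata for
the learning models and a design factor for the linkage analyses. Trials
are 0-based internally and 1-based in exported CSV.

## Learning models

Rescorla–Wagner updating per group with prediction error δ = R − V and
predicted rating β·V computed before the trial's update. Variants differ
only in how many learning-rate cells may differ: M1 (1), M2 (per group, 2),
M3 (per group × valence, 4). Parameters and bounds: α ∈ [0, 1] per cell,
β ∈ (0, 3] (lower bound 10⁻³ in the optimizer). Expectancy ratings are
treated on a normalized [0, 1] scale (they are subjective probability
estimates of a positive outcome); raw 10-step ratings should be divided by
10 on import.

**Initial values.** V(0) per group is set to the participant's first
observed rating for that group — a data-derived prior, not a free
parameter. Because the model's prediction is β·V, the first-trial
prediction β·rating₁ reproduces the datum only when β = 1; this mismatch is
inherent to using the first rating as the prior under multiplicative
response scaling. Each group's first trial is therefore excluded from the
fitted residuals. The synthetic generator adopts the mirror convention
(each group's first rating reports V(0) directly), which makes noise-free
round trips exact.

**Ties.** δ = 0 routes to the positive-valence cell; the update is a no-op
either way, the rule only fixes determinism.

**Single β.** β is shared across groups (the model family indexes V by
group but uses one response scaling); a per-group β would add a parameter
with no group-specific rating scale to justify it.

## Closeness models

The trial-wise change in closeness toward group *i* is affine in the
exponentially discounted sums of that group's past prediction errors —
signed (C1, one weight) or split by valence (C2, W_pos and W_neg). The
discount clock runs in absolute trial time: on the other group's trials the
group's sums receive an additional prediction error of zero, i.e. they keep
decaying by γ but nothing is added, so neither group's outcomes leak into
the other's closeness dynamics. Bounds: W ∈ [−10, 10] (10 = ceiling of the
closeness scale), W0 ∈ [0, 10], γ ∈ [0, 1]. γ = 1 weighs all past errors
equally; γ = 0 leaves only the current trial's error.

Observed changes are rating(t+1) − rating(t) on the 0–10 scale: closeness
is rated at the start of each trial, so the change induced by trial t's
outcome is observable only at t+1, and the final trial's prediction has no
observable counterpart and is dropped. Ingroup and outgroup series are
fitted separately with group-specific parameters (including separate W0 and
γ; the model family uses one γ across valences). W0 is fitted but treated
as a nuisance intercept; the substantive parameters are the weights and γ.

## Estimation

Least squares under a Gaussian observation model is the maximum-likelihood
estimate; σ is profiled out (σ̂² = SSE/n, ln L = −n/2·(ln 2πσ̂² + 1)).
Optimization is bounded quasi-Newton (L-BFGS-B — the bounds make plain BFGS
ill-posed at the edges) with default 10 restarts started uniformly within
the bounds from a seeded stream; best restart wins, non-convergence of all
restarts flags the result rather than raising. The closeness problem is
conditionally linear: for fixed γ the weights solve an OLS problem (with a
bounded linear solve when the unconstrained solution leaves the box), so γ
is profiled on a 201-point grid, refined by 1-D bounded search around the
best grid point, and the joint solution polished with L-BFGS-B; remaining
restarts attack the joint problem directly as a guard. Optimizer tolerances
are scipy defaults.

AIC = −2 ln L + 2k with k counting structural parameters only (M1/M2/M3:
2/3/5; C1/C2: 3/4); σ is profiled identically for every model and cancels
in comparisons. Variance explained is reported as the squared Pearson
correlation of observed and predicted series (the 1 − SSE/SST definition is
available as an option); zero-variance series yield NaN rather than a
fabricated value.

## Model comparison

Per-participant AICs are converted to approximate log evidence (−AIC/2; the
alternative −AIC convention gives identical rankings) and fed to
random-effects Bayesian model selection: a Dirichlet prior (α₀ = 1) over
population model frequencies, variational updates of per-subject model
responsibilities and the Dirichlet concentration to a 10⁻⁸ fixed point, and
exceedance probabilities estimated from 10⁶ seeded Monte-Carlo draws of the
posterior Dirichlet. For two models the XP has an exact Beta-CDF
expression, used as an independent oracle in the tests. A fixed-effects
summary (group-summed AIC) is reported alongside; winners within an XP
margin of 0.01 are flagged unresolved.

## Validation protocols

**Parameter recovery** draws true parameters uniformly within the fitting
bounds (learning: α ∈ [0,1] per cell, β ∈ [0.1, 3]; closeness: W ∈
[−10,10], W0 ∈ [0,10], γ ∈ [0,1]), simulates a fresh schedule and rating
series per dataset, refits with the participant-level estimator, and
reports per-parameter Pearson correlations over 100 simulations (the
package default). Recovery data are model-consistent: expectancy series are
β·V plus Gaussian noise without clipping, closeness-change series are the
model prediction plus noise, integrated into a rating series. Closeness
simulations are driven by the prediction errors of a fixed reference
learner (all α = 0.3, β = 1, V(0) = 0.5).

**Observation noise** is not part of the model specification and must be
chosen: defaults are σ = 0.15 on the [0,1] expectancy scale and σ = 1.0 on
the 0–10 closeness-change scale. At these levels the recovery floors are
noise-limited, not optimizer-limited (the profile-γ search solves the
conditional problem globally per grid point): the weakest learning
parameters are the valence-specific rates (only ~12 negative outcomes per
group per session), and the weakest closeness parameter is γ, which loses
identification when both weights are near zero — draws that uniform
sampling over [−10,10]² occasionally produces.

**Model identifiability** simulates cohorts (default 30 agents) from each
generating model, fits all candidates to every agent, declares the
cohort-level winner by group-summed AIC (XP-based winner available), and
repeats (default 10×) to fill a generating × winning confusion matrix.

## Synthetic populations

`sample_population` draws agents with culture-like profiles parameterized
from study-scale descriptives: identification 4.57 ± 1.15 (western) vs
5.75 ± 0.91 (east_asian) on a 1–7 scale, clipped; pre-learning impressions
on a 1–9 scale with ingroup above outgroup on average (5.99/5.68 western,
6.69/5.04 east_asian); initial ingroup bias drawn correlated with
identification (target r ≈ 0.26, bias spread 1.6). Learning rates are
uniform in [0,1], β uniform in [0.5, 1.5], V(0) in [0.2, 0.9]; closeness
weights uniform in [−5, 5] with small intercepts (W0 ∈ [0,1]) — a
realistic-agent range, narrower than the fitting bounds used in the
validation protocols.

`generate_session` integrates the agent's closeness dynamics into 0–10
rating series (clipping after noise; clipped trials retained) and anchors
the starting closeness to the pre-impression. Post-impressions follow a
transparent synthetic convention — the generative link between learning and
impression change is not part of the fitted model space, and exists solely
so the linkage analyses have recoverable structure: each group's
post-impression equals its pre-impression plus
`coupling × w_neg × mean discounted negative-PE sum (γ_ref = 0.5)` plus
noise (SD 0.3), with the coupling active only in the loss frame
(coupling 2.0) and attenuated linearly with identification
(`(7 − id)/3`, clipped to [0, 1.5]). Anchoring the drive to the
negative-PE component at a fixed reference horizon (rather than to the net
closeness change) keeps the planted association specific to W_neg and
approximately linear in it; the constants were calibrated once so the
planted impression shifts are sub-point in scale (SD ≈ 0.8) and the
loss-frame association is detectable at cohort sizes near 54. The
identification attenuation makes one convention reproduce both target
patterns: a direct loss-frame association in the lower-identification
(western-profile) cohort and an association visible only at low
identification in the higher-identification (east_asian-profile) cohort.

What the generator does *not* emulate: discrete 10-step response grids
(ratings are continuous), within-session drift or lapses, frame effects on
learning itself (frames share outcome sequences by construction),
questionnaire item structure, and any true causal mechanism from learning
to impressions. Passing linkage tests therefore demonstrate that the
analysis code detects structure of the planted form at realistic sizes —
not that real impression change arises this way.

## Linkage analyses

Intergroup impression change is (ingroup − outgroup) after minus before;
negative values mean the initial ingroup bias shrank. Stepwise regression
alternates forward steps (add the candidate with the smallest p below
`entry_p`) and backward steps (drop retained predictors above `removal_p`)
to a fixed point; thresholds default to the conventional 0.05/0.10 and are
reported with results; ties break by smaller p then name; collinear
candidate sets (condition number > 10⁸) drop the later duplicate with a
warning. Moderation centers the focal predictor and a continuous moderator
(binary moderators are coded 0/1), reports the interaction and simple
slopes at moderator mean ± 1 SD or per level, with slope variances from the
coefficient covariance. Influence diagnostics flag observations exceeding
any of |DFFITS| > 2√(k/n), Cook's D > 4/n, leverage > 2k/n, |DFBETA| > 1,
and report the refit excluding them whether or not conclusions change; on
clean Gaussian data these standard cutoffs flag a small fraction of
observations (order 5–10%), so "no flags at all" is not the expected null
behavior. The bias–identification correlation reports Pearson r with
Spearman ρ as robustness.

The linear-mixed-model analyses of raw ratings are deliberately not
reimplemented: the package exports tidy long-format tables
(`trials_table`, `participants_table`) for external mixed-model software.

## Problem sizes and determinism

Defaults follow the validation protocols: 100 recovery simulations, 30
agents × 10 repetitions for identifiability, 96-trial schedules throughout;
the analysis drivers use cohorts of 112 (western) and 100 (east_asian).
Module-level tests run reduced sizes of the same protocols. All randomness
flows through seeded `numpy` generators (`SeedSequence` spawning for
per-simulation streams), so every report is bit-reproducible under a fixed
seed. The RW recursion and discounted sums are JIT-compiled when numba is
available, with an identical pure-NumPy fallback.

## Known limitations

- The recovery floors depend on the assumed observation noise, which the
  model space does not constrain; they should be read as properties of the
  stated simulation conditions.
- AIC-as-evidence is an approximation (no parameter-volume term); protected
  exceedance probabilities and BIC/cross-validation alternatives are not
  implemented.
- The β–V(0) interaction under the first-rating prior convention biases the
  first prediction per group whenever β ≠ 1; residuals exclude those trials
  but the bias propagates into early-trial predictions at extreme β.
- Stepwise selection inherits the usual data-driven-selection caveats;
  p-values of selected coefficients are not selection-corrected.
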