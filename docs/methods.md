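# Methods

This note documents the modelling assumptions, numerical choices and known
limitations of `avoidgen`, in the spirit of a package methods appendix.
It states no empirical results beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## Task model and stimulus space

The avoidance task is represented as seven stimuli on a one-dimensional,
perceptually linear shape axis ρ ∈ (0, 1): CS+ at 0.25 and 0.75, a CS−
(default ρ = 0.40, configurable — deliberately asymmetric so one CS+ sits
nearer the safety cue, which is what makes peak shift measurable), and one
GS on each side of each CS+ at distance θ (default 0.071; the
crowdsourcing preset uses 0.065).  Each of the five blocks presents
10 CS−, 10 of each CS+, and 2 of each GS (38 trials; 190 total).
Unavoided CS+ trials deliver the aversive outcome with probability 0.8,
realized as independent Bernoulli draws (a per-block quota mode is
available as a switch); GS and CS− trials are structurally safe.
Pseudorandomization applies two constraints meant to minimize learning
about the rare GS trials: no two GS trials are adjacent, and no GS appears
in the first five trials of block 1.  These constraints are this package's
concrete reading of "pseudorandom"; sequences are reproducible from a
seed.

## Learning models

All variants are Q-learners over stimulus states with a single global
Pearce–Hall associability α_t (initialized at 1.0, configurable) and
outcomes coded 0 (safe) / −1 (shock or loss).  The value of avoiding is
pinned at 0 because avoidance deterministically prevents the outcome.
Choices are Bernoulli in P(avoid) = 1/(1 + exp(−β(0 − V_eff − 0.2 − bias))),
where 0.2 is the per-decision avoidance cost in outcome units.

Modelling decisions worth making explicit:

- **Initial values** are 0 for every stimulus — neutral on the {0, −1}
  outcome scale.
- **Associability is global and trial-varying**, and updates on every
  trial: on avoided trials the prediction error is identically 0, so
  α decays to (1 − η)α; on unavoided trials α ← η|PE| + (1 − η)α.
- **Perceptual confusion enters evaluation only.** A GS is evaluated as a
  25/75 mixture of its own value and its adjacent CS+ value (the 25%
  confusion probability corresponds to stimuli titrated to 75%
  discriminability), but learning always updates the objectively
  presented stimulus.  A LINEAR schedule interpolating the confusion
  probability across the session is available for testing whether
  discriminability drifts with conditioning.
- **Value spread** multiplies the presented stimulus's prediction error by
  Gaussian weights G_j = exp(−Δρ²/2σ²) and applies it to every stimulus,
  the presented one included (G = 1 there, so the rule nests the plain
  update).  The width is chosen by the *realized* outcome valence on that
  trial: σ_A after aversive, σ_N after neutral outcomes — including
  neutral outcomes on CS+ trials.  Setting σ_A = σ_N reproduces the
  one-width variant exactly (a unit test asserts this).
- **Values are not clipped** to [−1, 0].  The printed update rules do not
  bound them, and under spread the bound can genuinely fail.  In extreme
  corners of the parameter space the recursion can even diverge (large
  values feed the associability, which amplifies updates); the fitting
  objective maps non-finite evaluations to a large penalty so the
  optimizer simply avoids that region.

The per-trial likelihood loop is sequential, so the hot path is compiled
with numba; the readable single-trial functions (`step`, `p_avoid`,
`effective_nonavoid_value`) define the same dynamics and the test suite
checks the compiled path against an independently written naive loop to
1e-10 on 200 random fixtures.

## Hierarchical estimation

Free parameters are estimated on an unconstrained latent scale — logistic
for κ, η; log for β, σ_A, σ_N; identity for the bias — with independent
Gaussian priors (default N(0, 3), weakly informative; latent 0 maps to
κ = η = 0.5, β = σ = 1, bias = 0).  Subject fits are multistart L-BFGS-B
MAP estimates (8 starts: prior mean, seeded prior draws, and deterministic
±1.5-SD offsets along the σ latents, which are the directions prone to
narrow/wide local optima).  The latent search is boxed at |x| ≤ 10; this
excludes only numerically flat far tails (σ beyond e¹⁰ is behaviourally
indistinguishable from e³ on a unit axis).  The Laplace approximation uses
a central-difference Hessian (step 1e-4); non-positive-definite Hessians
are ridge-regularized and flagged.  The approximate log evidence is

    F = log p(y|θ*) + log p(θ*) − ½ log|H| + (d/2) log 2π,

and native-scale posterior variances for precision weights come from the
delta method.

Group fitting alternates subject MAP fits with a moment-matching update of
the prior (mean of posterior latents; their empirical variance plus the
mean posterior variance), stopping when the summed F changes by less than
`tol` (default 0.01, max 32 iterations; an infinite tolerance yields
exactly one round of independent fits).  Two stabilizations matter:

- **The refined prior variance is capped at its initial value.**  An
  uncapped moment update diverges whenever a parameter direction is
  unidentified for part of the cohort: a flat likelihood makes the
  posterior variance echo the prior variance, which re-enters the update
  and feeds back without bound.  Refinement may therefore only sharpen
  the weakly-informative prior, never widen it.
- **Divergence detection has its own margin (1 nat, 3 consecutive
  drops).**  Moment matching is not an ascent algorithm; near its fixed
  point the summed F oscillates by ~0.1 nats, and tying the divergence
  rule to the convergence tolerance would abort healthy fits.

Refinement rounds after the first use two warm starts (current prior mean
and the subject's previous optimum) rather than the full multistart,
which changes no result materially but keeps cohort fits fast.

## Model comparison

Random-effects BMS treats model identity as a random effect: a
variational Dirichlet update over model frequencies from subject-wise log
evidences, with exceedance probabilities by Monte Carlo over the Dirichlet
(10⁶ draws; the two-model case uses the exact Beta tail).  The prior
concentration is 1 per model.

Evidence for *comparison* is computed under the common fixed
weakly-informative prior (one round of independent fits), not under the
per-model refined priors.  Refined priors are optimized on the same data
the evidence is meant to judge, and for nested variants this double-dip
cancels the Occam penalty — the two-width model would beat the one-width
model even on one-width data.  Under the common prior the nested
comparison behaves correctly (the richer model pays roughly one nat per
subject when its extra width is superfluous), and the model-recovery test
requires the generating variant to win with exceedance probability ≥ 0.9
on 15-subject cohorts from each variant.  Hierarchical refinement remains
the estimator of choice for *parameters*.

## Psychophysics

Same/different discrimination is fitted with a lapse-bounded logistic
P(diff) = (1 − λ)/(1 + exp((α − Δρ)/β)) by binomial maximum likelihood
(guess rate fixed at 0; lapse constrained to [0, 0.06] by default; slope
forced positive because the shape axis is perceptually monotone).  Fits
use 10 multistarts inside the box.  The 75% threshold inverts the function
in closed form, θ = α − β·ln((1 − λ)/t − 1), and the round-trip is exact
to 1e-9.  Estimates landing on the location/slope box are flagged as
degenerate; a zero fitted lapse is not flagged (it is the expected
solution for clean data).

## Behavioural statistics

Relative avoidance z-scores the three role proportions (CS−, GS, CS+)
within participant; if all three are equal the z-values are defined as 0.
The peak-shift index averages, over CS+, avoidance of the flanking GS on
the side *away* from the CS− minus the side *toward* it, with near/far
assigned from ρ distances so the index survives axis counterbalancing.
QC filtering is sequential and order-dependent by construction: first
exclude CS+ avoidance strictly below 50%, then catch-item failures among
the survivors, each exclusion labelled with its rule.  The Nyholt
effective number of tests uses the sample (M−1 denominator) variance of
the correlation-matrix eigenvalues, m_eff = 1 + (M−1)(1 − Var(λ)/M), so
identity gives M and perfect correlation gives 1.  Precision-weighted
regression is ordinary WLS (statsmodels) with weights 1/posterior
variance — the ML estimator when measurement noise scales inversely with
the attached precision.

## Pattern distances

The crossnobis estimator computes, per leave-one-run-out fold, the dot
product of the training-runs' mean pattern difference with the held-out
run's difference, divided by the voxel count (so distances are comparable
across regions of different size; the normalization is configurable).
Cross-validation gives the statistic a meaningful zero: its expectation is
0 for identically distributed conditions and negative sample values are
legitimate.  Multivariate noise normalization whitens each run's patterns
by the inverse square root of its own residual covariance, shrunk toward
the diagonal (analytic shrinkage by default; shrinkage is forced to at
least 0.5 when residual samples are scarcer than voxels/10).  The
early/late distance-change statistic is the late-epoch minus early-epoch
distance (default epochs: runs 1–2 vs 3–5); negative values mean
conditions became more similar.

## Synthetic cohorts

The generator emulates the behavioural study conditions: per-subject
parameters are Gaussian on the latent scale around native-scale group
medians κ = 0.5, η = 0.3, β = 5, bias = 0.4, σ_A = 0.75, σ_N = 0.03, with
latent SDs of 0.5 (κ, η, σ_A, σ_N), 0.4 (β) and 0.15 (bias) — spreads
chosen once as realistic cohort heterogeneity on each parameter's scale.
Each subject gets a fresh pseudorandom sequence, simulated choices,
a 160-trial discrimination dataset (5 Δρ levels × 32 trials, generating
parameters placing the 75% threshold near 0.07), and a symptom score

    score = slope · z(log σ_A) + ε,   ε ~ N(0, noise/√precision),

with per-subject precisions drawn log-normally to emulate the unequal
reliability of posterior parameter estimates; the precision-weighted
regression stage is then the matching ML estimator of the planted slope
(default 0.04).  Presets: `fmri` (n = 26, θ = 0.071) and `amt`
(n = 482, θ = 0.065).  Everything derives from one master seed.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: reaction times, attention lapses and
stimulus-independent responding, questionnaire item-level structure,
session effects (the discrimination data are stationary), and fMRI
time-series noise (pattern datasets are Gaussian around condition means).

## Problem sizes and tolerances

The test suite and acceptance script use: 40 subjects × 190 trials for
parameter recovery (hierarchical fit, 8 refinement rounds), 15-subject
cohorts per variant for model recovery (single-round fixed-prior fits),
100-subject cohorts for the peak-shift contrast, 200 replicates for the
crossnobis null, 100 replicates each for threshold and symptom-slope
recovery, and 10⁶ Dirichlet draws for exceedance probabilities.  These
sizes were chosen so the full suite completes in about a minute while
keeping Monte-Carlo error well inside each assertion's tolerance — with
one knowing exception: the ±0.02 band on the perceptual-only peak-shift
mean sits at ~1.4 standard errors of its own cohort mean at n = 100, so
that check is intrinsically seed-sensitive.

## Known limitations

- Rank recovery of σ_A from 190-trial sessions is information-limited:
  only 20 GS trials probe generalization directly, and above roughly one
  stimulus spacing the Gaussian weights saturate, so large widths are
  barely distinguishable from each other.  Profiling the likelihood for
  σ_A with all other parameters held at their generating values raises
  rank recovery only modestly above the full joint fit, which places the
  achievable Spearman correlation at n = 40 near (and sometimes below)
  0.5.  Group means, σ_A > σ_N ordering, and model identity are recovered
  much more robustly than individual ranks.
- MAP + Laplace is an approximation to full variational inversion;
  absolute free-energy values are not comparable across toolboxes, and
  printed parameter estimates from studies fitted with other schemes are
  matched qualitatively, not numerically.
- The moment-matched group prior is diagonal; parameter correlations at
  the group level are not modelled.
- Exceedance probabilities are reported without protected/BOR variants.
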