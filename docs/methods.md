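# Methods

`adaptpe` simulates and analyses a reward-magnitude prediction experiment in
which a learner repeatedly predicts, on a £0–£100 scale, the size of a
reward drawn from one of six pseudo-Gaussian distributions (SD £5/£10/£15
crossed with EV £35/£65). The scientific object of interest is *adaptive
prediction-error (PE) coding*: scaling of the teaching signal δ = reward −
prediction relative to reward variability, both behaviourally (a learning
model whose updates divide the PE by a log-SD term) and neurally (PE
regression slopes that fall as SD grows, summarised by an SD⁻¹-weighted
contrast).

## Task generative model

An experiment is three sessions of 62 trials. Each session interleaves two
of the six distributions ("pots") in alternating blocks whose lengths are
drawn uniformly from {4, 5, 6}; the two pots always differ in *both* EV and
SD, and every pot contributes exactly 31 trials. Session pairings are drawn
uniformly from the set of perfect matchings of the six distributions under
the differ-in-both constraint (enumerated exhaustively — the same
enumeration doubles as a brute-force oracle in the tests).

Design choices where the design was genuinely open:

- **Pseudo-Gaussian rewards.** "Pseudo-Gaussian" is operationalised as
  moment matching: draw from a Gaussian truncated to [0, 100], affinely
  rescale so the *sample* mean and SD (ddof = 1) equal the nominal EV and
  SD, clip, round to £0.1, and redraw if the realised moments drift more
  than ±£0.5. Every agent therefore faces the nominal statistics, which the
  performance-error metric assumes.
- **Block schedule.** Strict block-by-block alternation between the two
  pots. Block lengths are sampled from the *feasible* subset of {4, 5, 6} —
  feasible meaning the pot's remaining trials can still be partitioned into
  in-range blocks — so every block, including each pot's last, stays within
  4–6 while the 31-trial totals hold exactly. (Naive truncation of a final
  block can produce 1–3-trial blocks, which would violate the design's own
  block-length range.)
- **Control trials.** Exactly `round(0.2·N)` trials per session (12 of 62)
  are control trials at pseudo-random positions. Control trials pay £7.50 /
  £5.00 / £2.50 for predictions within one SD / within two SDs / farther
  from the EV; test trials pay 10% of the drawn reward. Missed trials pay
  nothing and have reward and PE recorded as missing.
- **Precision.** Rewards, predictions and payoffs are stored to £0.1.

## Learning models

Predictions evolve by a delta rule μ′ = μ + k·δ with the four variants:

| model | learning rate | free parameters |
|---|---|---|
| RW1 | constant k | k, σ |
| RW2 | k₊ for δ ≥ 0, k₋ for δ < 0 | k₊, k₋, σ |
| PH1 | kₙ = (1−γ)·kₙ₋₁ + γ·C·\|δₙ\|/100, k₀ = k₁ | k₁, γ, σ |
| PH2 | as PH1, update uses δ/(D·ln SD)^ν | k₁, γ, ν, σ |

All rate-type parameters live on [0, 1]; μ is clipped to [0, 100] after
every update. C = D = 1 are fixed scaling constants (the |δ| term is
normalised by the 100-point scale), so they are not fitted. The natural log
is used in the PH2 denominator; with the task's SDs (≥ 5), ln SD > 1 and
scaling only ever shrinks the PE. ν = 0 reduces PH2 to PH1 exactly, and
k₊ = k₋ reduces RW2 to RW1 exactly — these nestings are enforced as
property tests, along with boundedness of μ and the dampening property
(identical δ produces a strictly smaller update under SD 15 than SD 5 when
ν > 0).

The exact published algebra of the Pearce–Hall variants is not available in
the source material; the recursions above are the simplest forms consistent
with every textual statement about them (rate driven by the absolute PE and
the previous rate with decay γ; PE divided by a log-SD term raised to ν).
The fitting machinery is agnostic to the step function, so a different PH
recursion could be swapped in without touching the estimation code.

**State bookkeeping.** One learner state per pot: the cue identifies the
distribution, and pot-specific state is the only reading consistent with
tracking two interleaved distributions of different EV.

**Simulation vs fitting direction.** A simulated agent emits
y = μ + 𝒩(0, σ), clipped and rounded, and then updates on the PE it
actually saw on screen (reward − *emitted* prediction). Fitting, by
contrast, folds the model-internal recursion (δ = reward − μ_model) over
the observed rewards, with each pot's initial mean pinned to its first
observed prediction (removing an unidentified initial condition). The mild
mismatch between the two directions is part of the study conditions; the
recovery suites quantify its effect (see below).

## Maximum-likelihood fitting

Predictions are modelled as y_m ~ 𝒩(μ_m, σ²). σ² has the closed-form MLE
Σ(y−μ)²/M, so it is profiled out analytically and the numeric search runs
over the learning parameters only: bounded L-BFGS-B from 20 (default)
Latin-hypercube starts, seed-controlled and bit-reproducible. A fit is
flagged converged when at least two restarts agree within 1e-4 nats.
σ² is floored at 1e-4 to keep noiseless synthetic input finite. AIC/BIC
count σ among the free parameters (RW1 = 2, RW2 = PH1 = 3, PH2 = 4) and M
counts non-missed trials.

An exhaustive grid evaluator over the same profiled objective serves as an
independent oracle: the optimiser must never fall more than 1e-3 nats below
the grid optimum (checked on 20 random 60-trial datasets per model).

Recovery at study scale (186 trials), measured by the test suite: RW1's k
is recovered within ±0.1 in ≥ 90% of seeds; for PH2 with ν ∈ {0, 0.3, 0.7,
1.0} and random (k₁, γ, σ), the median |ν̂ − ν| is ≈ 0.09 and
scaler/non-scaler classification (ν̂ > 10⁻³) is ≈ 88% correct. True
non-scalers land exactly on the ν = 0 boundary in roughly half of fits —
boundary MLEs are genuine, which is why the scaler threshold is a small
ε = 10⁻³ rather than 0.

Model comparison reports, per ordered model pair, the mean across agents of
(criterion_row − criterion_col) for AIC and BIC (negative favours the row
model), plus each agent's best model by BIC with ties broken toward fewer
parameters. On PH2-generated cohorts both criteria favour PH2 over all
three alternatives in every replicate cohort tested.

## Behavioural analyses

- **Performance error**: mean |prediction − EV| over non-missed trials, per
  SD condition and overall (the EV is the optimal prediction, so this is
  regret against the ideal observer). Even the optimal running-mean agent's
  error grows with SD — the task's manipulation check, asserted over 100
  seeded experiments.
- **Scaler contingency**: counts of ν̂ ≤ ε vs ν̂ > ε by group, compared with
  a Pearson χ² *without* continuity correction (the variant that reproduces
  the worked example 5.27 from counts 8/19 vs 2/20 at two decimals).
- **Residualisation**: z-scored OLS residuals of an outcome on a nuisance
  covariate (emulating time-from-dosing-to-scan), applied before group
  comparisons.
- **Group tests**: one-way ANOVA with two-sample-t post hocs for
  (approximately normal) behavioural metrics; Kruskal–Wallis with rank-sum
  post hocs otherwise. Post hocs are restricted to control-vs-treatment
  pairs at α = 0.025 (Bonferroni for two comparisons).
- **Performance regression**: overall performance error on {scaler
  indicator, k₁, γ} with treatment group as a categorical covariate. The
  scaler enters as presence/absence, not continuous ν.
- **Model R²**: squared correlation between observed predictions and
  model-predicted means, averaged over SD conditions.

## Neural adaptation

Trial-wise ROI-like responses replace BOLD time series; there is no HRF
convolution, motion modelling or voxel-wise correction — the inferential
chain the group statistics need (PE slopes per SD × PE-sign → weighted
contrast → rank tests) operates at the ROI-summary level.

- **Forward model**: response = β₀ + β_value·reward + β_pe(SD, sign)·δ +
  𝒩(0, noise_sd), with β_pe(SD) = base·(1 + a·(5/SD − 1)) and a ∈ [0, 1]
  the adaptation strength (a = 0: flat slopes; a = 1: slopes ∝ 1/SD, ratio
  3 between SD 5 and SD 15). Positive- and negative-PE base slopes may
  differ. δ = 0 trials are deterministically assigned to the positive cell.
- **Estimation**: per SD × sign cell (≥ 5 trials required), OLS of the
  response on {1, value, PE}, with the PE regressor first residualised
  against {1, value} (serial orthogonalisation, so PE only captures
  variance not attributable to reward magnitude). Noiseless recovery is
  exact to ≈ 1e-6 and the error shrinks with the noise level.
- **Contrast**: weights ∝ 1/SD, mean-centred to sum to zero — so flat
  slopes give exactly 0 and slopes falling with SD give a positive value.
  For {5, 10, 15}: [0.0778, −0.0222, −0.0556]. Centring is a convention;
  any affine-equivalent weighting yields identical rank-test results.
- **Group comparison**: Kruskal–Wallis omnibus, rank-sum post hocs
  (control vs each treatment, α = 0.025), and a one-sided signed-rank test
  that the control group's contrast exceeds zero.

## Synthetic cohorts

The study driver's default cohort is three groups of 19 agents, all
generated from PH2. The group regimes encode the qualitative pattern the
pipeline should detect: the placebo-like group draws ν from U(0.5, 1) with
a 10% chance of ν = 0 and strong neural adaptation (a ∈ [0.6, 1]); the
sulpiride-like group has a 40% non-scaler probability, lower k₁
(U(0.3, 0.7)), higher response noise, and weak neural adaptation
(a ∈ [0, 0.25]); the bromocriptine-like group sits near placebo. The
dose-to-scan covariate is Gaussian per group (means ≈ 167/168/161 min, SDs
9–12). A global seed fans out through fixed per-stage, per-agent
`SeedSequence` substreams keyed by the agent's global index, so growing the
cohort never perturbs earlier agents.

What the generator does *not* emulate: real response times, trackball
kinematics, within-session drift or fatigue, heavy-tailed or autocorrelated
neural noise, and between-subject correlation structure beyond the group
regimes. Passing tests therefore demonstrate that the estimation machinery
is correct and adequately powered under the stated conditions, not that the
effects exist in any particular empirical dataset.

## Numerical choices and degenerate inputs

- σ² floor 1e-4; convergence tolerance between restarts 1e-4 nats;
  optimiser-vs-oracle slack 1e-3 nats.
- Fitting requires ≥ 30 non-missed trials; slope cells require ≥ 5 trials.
- Ties in best-model selection go to the model with fewer parameters.
- Residualisation rejects constant covariates and fully-explained outcomes;
  contingency χ² rejects zero marginals; group tests reject singleton
  groups and flag any group smaller than 5 as under-powered.
- PH1 on a constant reward stream converges to the reward at rate O(1/n)
  (the rate decays with the shrinking |δ|), which the stability test
  asserts as a monotone approach rather than exact attainment.

## Problem sizes used by the test suite

Heavy suites are scaled to keep the default run fast while leaving the
statistical assertions well-resolved: oracle checks use 60-trial datasets
(10 trials per pot); parameter recovery uses 50 RW1 agents and 100 PH2
agents at the full 186 trials; model-selection recovery uses 5 replicate
cohorts of 6 agents with 10 restarts; neural power uses 15 replicate
two-group cohorts of N = 19; null calibrations use 2000 draws at the
test-statistic level.

## Known limitations

- The PH recursions are a reconstruction (see above); parameter *values*
  fitted here are not comparable to those from any other implementation of
  a Pearce–Hall-family model.
- ν is weakly identified when the true value is small but nonzero
  (ν ≈ 0.3 fits shrink toward 0), so non-scaler counts are conservative.
- The profiled σ is a single per-agent noise level; condition-specific
  response noise is not modelled.
- The neural forward model is linear with Gaussian noise; the contrast's
  null calibration is exact under exchangeability but the power figures are
  specific to the default noise regime (noise_sd = 2 a.u., base slope 1).
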