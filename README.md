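# adaptpe

Simulation and model-based analysis of **reward prediction under variable
rewards**, for computational cognitive neuroscientists studying adaptive
prediction-error (PE) coding.

In the task this package models, a learner predicts the magnitude of an
upcoming reward on a £0–£100 scale. Rewards are drawn from one of six
pseudo-Gaussian distributions crossing a standard deviation of £5/£10/£15
with an expected value of £35/£65; cues signal only the *relative*
variability. Efficient learners are expected to scale the trial-by-trial
prediction error δₙ = rₙ − yₙ relative to reward variability — updating
strongly when PEs are precise and restraining learning when they fluctuate —
and neural PE responses are expected to show the same adaptation: PE
regression slopes that fall as SD grows.

The package provides:

- **Task generator** — sessions of alternating 4–6-trial blocks of two
  distributions (differing in both EV and SD), 31 trials per distribution,
  moment-matched rewards, 20% accuracy-paid control trials, full payoff
  rules, reproducible seeding.
- **Learning models** — four delta-rule variants, fitted or simulated:
  Rescorla–Wagner with one rate (RW1) or asymmetric rates for ±PEs (RW2),
  Pearce–Hall with a dynamic rate kₙ = (1−γ)kₙ₋₁ + γ·|δₙ|/100 (PH1), and
  the adaptive variant whose update divides the PE by (ln SD)^ν (PH2);
  ν ∈ [0, 1] is the extent of PE scaling, ν = 0 meaning none.
- **Fitting** — per-agent maximum likelihood under y_m ~ 𝒩(μ_m, σ²) with σ²
  profiled analytically, multi-start bounded optimisation, a brute-force
  grid oracle, and AIC/BIC model comparison (pairwise mean criterion
  differences across agents; negative favours the row model).
- **Behavioural statistics** — performance error |y − EV| per SD condition,
  scaler/non-scaler contingency with Pearson χ² (no continuity correction),
  covariate residualisation, ANOVA/Kruskal–Wallis group tests with
  control-vs-treatment post hocs at α = 0.025, and a regression of
  performance error on the fitted learning parameters.
- **Neural adaptation** — trial-wise ROI-like responses with SD- and
  sign-dependent PE slopes, slope estimation with the PE regressor
  orthogonalised to outcome value, the mean-centred SD⁻¹-weighted
  adaptive-coding contrast, and rank-based group comparisons.

See `docs/methods.md` for the models, assumptions and numerical choices.

## Worked example

Run a reduced synthetic study (three groups of 8 agents; the default is
19 per group) end to end:

```python
from adaptpe import StudyConfig, GroupSpec, run_study

cfg = StudyConfig(
    groups={
        "placebo": GroupSpec(n=8),
        "bromocriptine": GroupSpec(n=8, p_nonscaler=0.15,
                                   adaptation_strength=(0.5, 0.9)),
        "sulpiride": GroupSpec(n=8, k1=(0.3, 0.7), p_nonscaler=0.4,
                               sigma=(3.0, 6.0),
                               adaptation_strength=(0.0, 0.25)),
    },
    n_restarts=10,
)
run_study(cfg, seed=7, outdir="demo_study")
```

This writes trial tables, fit results, the model-comparison table,
behavioural statistics and neural contrasts under `demo_study/`. With seed
7 the summary contains, among others:

```
PH2 vs RW1:  dAIC = -47.0   dBIC = -40.5
PH2 vs PH1:  dAIC =  -7.8   dBIC =  -4.6
neural adaptive contrast, Kruskal-Wallis: H = 15.86, p = 0.00036
  placebo vs sulpiride rank-sum: p = 0.00078  (significant at 0.025)
  placebo vs bromocriptine rank-sum: p = 0.29
placebo contrast > 0 (signed-rank, one-sided): p = 0.0039
```

Read: every agent was generated from the adaptive Pearce–Hall model, and
both information criteria correctly prefer PH2 over the three simpler
models (negative differences favour the row model). The sulpiride-like
group was generated with weak neural adaptation, and the SD⁻¹-weighted
contrast pipeline detects exactly that group difference while the
placebo-like group shows reliably positive adaptive coding.

The same pipeline is available from the shell:

```sh
adaptpe simulate-task --seed 3 --out design.csv
adaptpe run-study --seed 7 --out demo_study
adaptpe fit --in trials.csv --models RW1,RW2,PH1,PH2 --restarts 20 \
        --seed 1 --out fits/
adaptpe compare --fits fits/ --out comparison.csv
```

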