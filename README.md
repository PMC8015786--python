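# guildgrowth

Hierarchical Bayesian state-space modelling of multispecies fish population
growth from long-term trawl surveys, with partial pooling across functional
feeding groups and a zooplankton-biomass covariate.

## The science

Long-term nearshore trawl surveys count fish of many species year after
year, but each species' series is short, noisy and zero-inflated, and the
survey design itself changes over the decades (sites added, sampling effort
reduced). `guildgrowth` implements a joint model for such data in the style
of multispecies state-space analyses of the Lake Michigan nearshore fish
community:

- each species' log abundance follows a discrete-time exponential-growth
  random walk, `n[s,t+1] = n[s,t] + λ[s,t]`;
- annual growth rates λ are partially pooled within *functional feeding
  groups* (benthic invertivores, general invertivores, planktivores), so
  data-rich species inform data-poor ones that feed the same way;
- the study period is split into two regimes: in the early regime growth
  varies around a group mean `λ̄_f`, and in the later regime — after a
  large-scale change in the prey base — the group mean growth becomes a
  linear function of standardized zooplankton biomass,
  `α_f + β_f · x[t]`;
- raw trawl counts are linked to the latent states through a
  Poisson–lognormal observation model with site-level catchability offsets
  `γ[s,site]` and per-event overdispersion, so changes in the site roster
  and sampling intensity are handled in the likelihood rather than by
  pre-averaging.

The package provides the data layer (survey and covariate readers, CPUE
summaries, model-input assembly), a forward simulator for the same survey
design, the posterior sampler, convergence diagnostics, the derived
posterior tables (species growth trajectories, group process SDs, regime
mean growth, growth-vs-zooplankton curves and slopes), and a pipeline /
CLI that runs everything end to end with a reproducibility manifest.

## Worked example

Simulate a reduced five-species survey (15 years, an era change in sites
and effort, regime change in 2008), fit it, and summarize the group-level
posterior:

```python
import numpy as np
from guildgrowth import (Era, MCMCConfig, SimulationConfig, fit,
                         simulate_dataset, summarize, slope_summary)

config = SimulationConfig(
    group_map={
        "B1": "benthic invertivore", "B2": "benthic invertivore",
        "G1": "general invertivore", "G2": "general invertivore",
        "P1": "planktivore",
    },
    eras=(
        Era(2001, 2010, ("M", "K"), (6, 7, 8), 1),
        Era(2011, 2015, ("M", "K", "G"), (8,), 1),
    ),
    covariate_start=2008,
    n1={"B1": 1.5, "B2": 2.5, "G1": 4.0, "G2": 3.0, "P1": 3.5},
    beta={"benthic invertivore": -0.07, "general invertivore": -0.19,
          "planktivore": 0.22},
)
dataset = simulate_dataset(config, seed=11)
inputs = dataset.to_model_inputs()
print(f"{inputs.n_obs} observations, {inputs.n_species} species, "
      f"{inputs.n_years} years")

draws = fit(inputs, MCMCConfig(chains=3, iterations=3000, warmup=1200,
                               target_accept=0.95), seed=11)
summary = summarize(draws, blocks=["lambda_bar", "alpha", "beta"])
print(summary.round(3).to_string(index=False))
print(slope_summary(draws).round(3).to_string(index=False))
```

Output (seed-deterministic; ~40 s on one CPU):

```
375 observations, 5 species, 15 years
                      parameter  median  lower95  upper95  rhat
lambda_bar[benthic invertivore]  -0.008   -0.357    0.325 1.006
lambda_bar[general invertivore]   0.041   -0.104    0.181 1.019
        lambda_bar[planktivore]  -0.008   -0.371    0.297 1.022
     alpha[benthic invertivore]  -0.207   -0.582    0.142 1.007
     alpha[general invertivore]  -0.074   -0.231    0.091 1.006
             alpha[planktivore]   0.053   -0.255    0.305 1.023
      beta[benthic invertivore]  -0.078   -0.555    0.405 1.004
      beta[general invertivore]  -0.248   -0.471   -0.004 1.019
              beta[planktivore]   0.257   -0.171    0.698 1.046

              group  median  lower95  upper95
benthic invertivore  -0.078   -0.555    0.405
general invertivore  -0.248   -0.471   -0.004
        planktivore   0.257   -0.171    0.698
```

The fitted slope medians (−0.078, −0.248, 0.257) recover the simulated
truth (−0.07, −0.19, 0.22) with every true value inside its 95% credible
interval. In this small demo the split of the overall catch level between
the initial log abundance `n1` and the site offsets `γ` is only weakly
identified (2–3 sites), so those nuisance parameters carry the largest
split-R̂ (up to ≈1.3 here); all group-level parameters converge
(R̂ ≤ 1.05).

## Command line

```bash
guildgrowth simulate --config cfg.yml --seed 1 --out data/        # survey.csv, covariate.csv, truth.json
guildgrowth fit --survey data/survey.csv --covariate data/covariate.csv \
    --config cfg.yml --seed 1 --out fit/                          # saved draws
guildgrowth summarize --draws fit/ --derived --out summary/       # summary.csv + derived tables
guildgrowth pipeline --config cfg.yml --seed 1 --out runs/demo    # everything, with manifest.json
guildgrowth recover --config cfg.yml --replicates 20 --seed 1     # CRI coverage study
```

A config is a YAML file with a `simulation` block (or a `data` block
pointing at survey/covariate CSVs plus a `groups` species→group mapping)
and an optional `mcmc` block (`chains`, `iterations`, `warmup`,
`target_accept`, …).

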