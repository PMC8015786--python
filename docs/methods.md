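# Methods

This document states the model exactly as implemented, lists every
parameter and default with its rationale, describes what the forward
simulator emulates, and records the numerical choices and known
limitations.

## 1. Model

### State process

Indices: species `s = 1..S`, study years `t = 1..T` (calendar years
`years[0]..years[T-1]`), functional feeding groups `f = 1..F` with a fixed
species→group map `f(s)`, trawl sites within the roster of each era, and
observation events `i = 1..N`.

Log abundance (on the scale of expected catch per unit effort) follows a
discrete-time exponential-growth random walk:

```
n[s, t+1] = n[s, t] + λ[s, t]            t = 1..T-1
n[s, 1]   ~ Normal(0, 2)
```

Growth rates are partially pooled within groups, with the pooling
distribution switching at a fixed regime boundary (the calendar year from
which the covariate series is used, `covariate_start`):

```
regime 1 (origin year < covariate_start):  λ[s,t] ~ Normal(λ̄_f(s), σ_λ,f(s))
regime 2 (origin year ≥ covariate_start):  λ[s,t] ~ Normal(α_f(s) + β_f(s)·x[t], σ_λ,f(s))
```

`x[t]` is the zooplankton biomass of the transition's origin year,
z-scored with the covariate series' own mean and SD (ddof = 1). The
transition from year `t` to `t+1` is attributed to origin year `t`.

### Observation process

Each survey event `i` (a single trawl tow identified by year, month, site,
event number) yields a count for every species in the roster — absent
species are explicit zeros:

```
y[i] ~ Poisson( effort[i] · exp( n[s(i), t(i)] + γ[s(i), site(i)] + ε[i] ) )
γ[s, site] ~ Normal(0, σ_γ,s)         site-level catchability offset
ε[i]       ~ Normal(0, σ_ε,s(i))      per-event lognormal overdispersion
```

Effort defaults to 1.0 (one standardized tow-hour). Because the site
roster and within-year sampling intensity enter the likelihood event by
event, design changes across eras need no pre-averaging or reweighting.

### Priors

All location-type parameters (`λ̄_f`, `α_f`, `β_f`, `n[s,1]`) get
`Normal(0, 2)`; all standard deviations (`σ_λ,f`, `σ_γ,s`, `σ_ε,s`) get
`half-Cauchy(0, 2)`. These are weakly informative on the log scale, where
plausible annual growth rates are order 0.1–1. An option
(`shared_obs_sigmas`) collapses the per-species `σ_γ,s`, `σ_ε,s` to single
shared values.

## 2. Parameters and defaults

| Parameter | Default | Why |
|---|---|---|
| `F` groups | 3 (benthic invertivore, general invertivore, planktivore) | functional feeding guilds of a nearshore Great Lakes fish community |
| default roster | 10 species (4/3/3 across the groups) | mirrors a long-running beach-seine/trawl roster |
| study span | 1984–2016 (T = 33) | multi-decadal series spanning the prey-base regime change |
| `covariate_start` | 1997 | onset of the zooplankton-driven regime (dreissenid-era prey decline) |
| site eras | 2 sites ('84–'88) → 3 ('89–'09) → 4 ('10–'16) | the design change the observation model must absorb |
| events | Jun–Aug, 2/site/month, dropping to one August tow from 2010 | the historical effort reduction |
| effort | 1.0 h per event | standardized tow |
| MCMC protocol | 3 chains × 5,000 iterations, first 2,000 discarded (9,000 saved) | convention for analyses of this size; see §4 |
| `target_accept` | 0.9 | hierarchical scale parameters create funnel-like geometry; high targets reduce divergences |
| convergence rule | split-R̂ < 1.1 on reported blocks | standard threshold |

Simulator truth defaults (all overridable): group mean growths
`λ̄ = (0.05, 0.0, −0.05)`, process SDs `σ_λ = (0.5, 0.2, 0.6)`, regime-2
intercepts `α = (−0.05, −0.1, −0.15)` and slopes
`β = (−0.07, −0.19, 0.22)` for (benthic, general, planktivore);
`σ_ε = 0.7`, `σ_γ = 0.5`; covariate level ≈ 50,000 mg/m³ declining ~8%/yr
with lognormal noise 0.35. These magnitudes match what long-term Great
Lakes survey analyses report for guild-level growth and catch
overdispersion, so simulation studies stress the sampler at realistic
signal-to-noise.

## 3. What the simulator emulates (and what it doesn't)

`simulate_dataset` draws the covariate series, the group-structured growth
rates, the latent log-abundance trajectories, site offsets, and per-event
Poisson–lognormal counts under exactly the fitted model's assumptions, for
an arbitrary era design. It emulates: era-varying site rosters and
sampling effort, regime switching tied to the covariate onset, explicit
zeros for absent species, and species-level overdispersion. It does not
emulate: gear or seasonal catchability trends, species interactions,
age/size structure, immigration pulses, or covariate measurement error —
the generator is the model, so recovery studies test inference, not model
misspecification. Latent log means are capped (`log_mu_cap = 25`, with a
warning) to keep pathological parameter draws from overflowing counts.

## 4. Computation

### Sampler

Posterior sampling is plain Hamiltonian Monte Carlo with a Metropolis
correction (`_hmc.py`): jittered-length leapfrog trajectories (nominal
integration time 1.2, length drawn uniformly in [0.5, 1]× the nominal
step count, capped at 96 steps), Nesterov dual averaging of the step size
toward the target acceptance rate, and Stan-style doubling windows over
[0.15, 0.9] of warmup for a regularized diagonal mass matrix; step-size
adaptation restarts after each mass update. A transition whose Hamiltonian
error exceeds 1000 is counted as divergent; a fit aborts if more than 30%
of saved draws diverge.

### Parameterization

The sampler works on an unconstrained vector: the latent states `n[s,t]`
are sampled directly (growth rates are the first differences, a
unit-Jacobian linear map), the site and event effects are non-centered
(`γ = σ_γ·z`), and all SDs are log-transformed with the Jacobian added.
Sampling the states rather than the increments is essential here: event
counts are directly informative about each `n[s,t]`, and the incremental
parameterization induces long-range posterior correlations that HMC with a
diagonal mass matrix cannot traverse. Two invariants are enforced by
tests: the unconstrained log density equals the centered joint posterior
plus the log-Jacobian (to 1e-8 on random fixtures), and the sampler
reproduces the closed-form posterior of a conjugate special case in which
every block except `λ̄` is held fixed.

### Fast path

The all-blocks-free gradient is evaluated by a numba-compiled kernel
(`_kernels.py`), ~30× faster than the numpy reference; the numpy
implementation (`UnconstrainedPosterior._logp_and_grad`) remains the
source of truth and the test suite asserts machine-precision agreement.
Fits with fixed blocks use the numpy path.

### Fixed blocks and point masses

Any parameter block can be held fixed for validation studies. A fixed
`σ = 0` is a point mass: the corresponding effects must also be fixed at
zero, and both drop out of the density. This is what makes the conjugate
oracle exact.

### Diagnostics and summaries

Split-R̂ follows the half-chain formula
`sqrt(((N−1)/N·W + B/N)/W)` on 2M half-chains, with a rank-normalized
(Blom scores) variant behind a flag; constant chains return exactly 1.0
with a warning. Posterior tables report the median and equal-tailed 95%
credible interval (type-7 quantiles), computed per draw for derived
quantities (trajectories, regime means, growth-vs-covariate curves,
slopes) before summarizing.

### Reproducibility

All randomness descends from a single integer seed through
`numpy.random.SeedSequence` substreams (per simulator component, per
chain, per recovery replicate), so every fit, pipeline run, and study is
bit-reproducible. Pipeline runs write a manifest with config hash, seed,
backend identifier, and input SHA-256 checksums.

## 5. Validation evidence

The statistical test suite (`tests/test_acceptance.py`,
`scripts/acceptance.py`) checks, at a reduced 5-species/15-year design:
density-decomposition and kernel agreement to machine precision;
conjugate-case posterior mean within 3 Monte-Carlo SEs; the split-R̂
formula to 1e-12; Poisson mean–variance structure of simulated counts
(with overdispersion appearing when `σ_ε > 0`); ≥80% empirical coverage of
95% credible intervals for all 12 group-level parameters over 20
simulate–fit replicates; and slope credible intervals containing zero in
≥90% of replicates when the true covariate effect is null.

## 6. Limitations

- The regime boundary is fixed by the covariate onset year, not estimated.
- The split between initial log abundance `n[s,1]` and site offsets
  `γ[s,·]` is weakly identified when sites are few; those nuisance
  parameters mix slowest and can keep split-R̂ above 1.1 at short chain
  lengths even when all group-level parameters have converged. Longer
  chains (the default protocol) or a sum-to-zero constraint on `γ` would
  tighten this; the constraint is not imposed to keep the model exactly as
  stated.
- Plain HMC with jittered trajectory lengths is exact but less efficient
  than NUTS; divergence rates of 0.1–1% at `target_accept` 0.9–0.95 are
  typical on hierarchical-funnel geometry and are reported per fit.
- Per-event overdispersion draws `ε[i]` are sampled but not stored by
  default (`save_eps`), since at full scale they dominate memory and no
  reported summary uses them.
- The Poisson–lognormal observation model has no separate zero-inflation
  component; structural zeros (species truly absent from a site) load on
  the site offsets.
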