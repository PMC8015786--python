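"""Forward simulation of the multispecies trawl survey.

Generates complete datasets (latent log-abundance trajectories, growth-rate
draws, overdispersed Poisson counts on an unbalanced site roster, and an
annual covariate series) from the same generative model the inference module
fits, so the full pipeline is testable without any field data.

The default configuration mirrors the southern Lake Michigan survey design:
10 species in 3 functional feeding groups (4 benthic invertivore, 3 general
invertivore, 3 planktivore), 33 annual time steps (1984–2016), a site roster
growing 2 → 3 → 4 across three eras, six 1-h trawl events per site-year in
the dense era (twice monthly, June–August) and one in the sparse era
(August only), and a declining zooplankton biomass covariate covering the
last 19 year-transitions (1997–2015).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .data_io import (
    GROUP_LABELS,
    CovariateSeries,
    DataValidationError,
    FunctionalGroupMap,
    ModelInputs,
    StudyConfig,
    SurveyObservation,
    build_model_inputs,
)

#: maximum tolerated log event mean before an event is flagged as overflowing
DEFAULT_LOG_MU_CAP = 25.0  # exp(25) ≈ 7e10 fish: far beyond any real trawl


@dataclass(frozen=True)
class Era:
    """A block of survey years sharing a site roster and sampling intensity."""

    start_year: int
    end_year: int
    sites: tuple[str, ...]
    months: tuple[int, ...]
    events_per_site_month: int


DEFAULT_ERAS = (
    Era(1984, 1988, ("M", "K"), (6, 7, 8), 2),
    Era(1989, 2009, ("M", "K", "G"), (6, 7, 8), 2),
    Era(2010, 2016, ("M", "K", "G", "E"), (8,), 1),
)

DEFAULT_GROUP_MAP = {
    "JOD": "benthic invertivore",
    "ROG": "benthic invertivore",
    "LOS": "benthic invertivore",
    "WHS": "benthic invertivore",
    "YEP": "general invertivore",
    "SPS": "general invertivore",
    "TRP": "general invertivore",
    "ALE": "planktivore",
    "RAS": "planktivore",
    "BLO": "planktivore",
}

# guild-level truth: log-growth near zero (stable populations), planktivores
# and benthic invertivores more variable than general invertivores, covariate
# slopes of the magnitudes seen in Great Lakes planktivore/invertivore data
DEFAULT_LAMBDA_BAR = {
    "benthic invertivore": 0.05,
    "general invertivore": 0.0,
    "planktivore": -0.05,
}
DEFAULT_SIGMA_LAM = {
    "benthic invertivore": 0.5,
    "general invertivore": 0.2,
    "planktivore": 0.6,
}
DEFAULT_ALPHA = {
    "benthic invertivore": -0.05,
    "general invertivore": -0.1,
    "planktivore": -0.15,
}
DEFAULT_BETA = {
    "benthic invertivore": -0.07,
    "general invertivore": -0.19,
    "planktivore": 0.22,
}

# initial log-abundance per species, on the scale of observed annual CPUE
DEFAULT_N1 = {
    "JOD": 1.0, "ROG": 0.5, "LOS": 0.0, "WHS": -0.5,
    "YEP": 5.5, "SPS": 5.5, "TRP": 2.0,
    "ALE": 4.5, "RAS": 3.0, "BLO": 3.0,
}


@dataclass
class SimulationConfig:
    """True-value counterpart of every model unknown, plus the survey design."""

    group_map: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_GROUP_MAP))
    eras: tuple[Era, ...] = DEFAULT_ERAS
    covariate_start: int = 1997
    lambda_bar: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LAMBDA_BAR))
    sigma_lam: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SIGMA_LAM))
    alpha: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_ALPHA))
    beta: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BETA))
    n1: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_N1))
    sigma_eps: float | dict[str, float] = 0.7
    sigma_gamma: float | dict[str, float] = 0.5
    covariate_level: float = 50_000.0
    covariate_trend: float = -0.08
    covariate_noise_sd: float = 0.35
    log_mu_cap: float = DEFAULT_LOG_MU_CAP

    def __post_init__(self) -> None:
        self.groups = [g for g in GROUP_LABELS if g in set(self.group_map.values())]
        self.species = sorted(self.group_map)
        missing = set(self.species) - set(self.n1)
        if missing:
            raise DataValidationError(f"n1 missing for species {sorted(missing)}")
        if isinstance(self.sigma_eps, (int, float)):
            self.sigma_eps = {s: float(self.sigma_eps) for s in self.species}
        if isinstance(self.sigma_gamma, (int, float)):
            self.sigma_gamma = {s: float(self.sigma_gamma) for s in self.species}
        for name, d in [("sigma_lam", self.sigma_lam), ("sigma_eps", self.sigma_eps),
                        ("sigma_gamma", self.sigma_gamma)]:
            if any(v < 0 for v in d.values()):
                raise DataValidationError(f"{name} must be >= 0")
        for e in self.eras:
            if e.events_per_site_month < 1:
                raise DataValidationError("events_per_site_month must be >= 1")
        if not self.start_year < self.covariate_start <= self.end_year:
            raise DataValidationError(
                "covariate onset must fall inside the study span (after year 1)"
            )

    @property
    def start_year(self) -> int:
        return min(e.start_year for e in self.eras)

    @property
    def end_year(self) -> int:
        return max(e.end_year for e in self.eras)

    @property
    def n_years(self) -> int:
        return self.end_year - self.start_year + 1

    @property
    def study(self) -> StudyConfig:
        return StudyConfig(self.start_year, self.end_year)

    @property
    def functional_groups(self) -> FunctionalGroupMap:
        return FunctionalGroupMap(self.group_map)

    def group_of(self, species: str) -> str:
        return self.group_map[species]

    def era_of(self, year: int) -> Era:
        for e in self.eras:
            if e.start_year <= year <= e.end_year:
                return e
        raise KeyError(f"year {year} outside all eras")


@dataclass
class SimulatedDataset:
    """One forward draw: observations, covariate, and the generating truth."""

    config: SimulationConfig
    observations: list[SurveyObservation]
    covariate: CovariateSeries
    latent_states: np.ndarray      # (S, T) true log-abundance
    growth_rates: np.ndarray       # (S, T-1) true log-growth draws
    site_effects: dict[tuple[str, str], float]  # (species, site) -> gamma
    overflow_events: list[tuple]   # flagged events whose log-mean hit the cap
    seed: int

    def to_model_inputs(self) -> ModelInputs:
        return build_model_inputs(
            self.observations, self.covariate, self.config.functional_groups,
            self.config.study,
        )

    def truth_dict(self) -> dict:
        """JSON-serializable record of the generating parameters and states."""
        cfg = self.config
        return {
            "seed": self.seed,
            "species": cfg.species,
            "groups": cfg.groups,
            "lambda_bar": cfg.lambda_bar,
            "sigma_lam": cfg.sigma_lam,
            "alpha": cfg.alpha,
            "beta": cfg.beta,
            "n1": cfg.n1,
            "sigma_eps": cfg.sigma_eps,
            "sigma_gamma": cfg.sigma_gamma,
            "latent_states": {
                s: self.latent_states[i].tolist() for i, s in enumerate(cfg.species)
            },
            "growth_rates": {
                s: self.growth_rates[i].tolist() for i, s in enumerate(cfg.species)
            },
            "site_effects": {f"{sp}:{site}": g
                             for (sp, site), g in self.site_effects.items()},
        }


# ---------------------------------------------------------------------------
# component simulators
# ---------------------------------------------------------------------------


def _rng_streams(seed: int, n: int) -> list[np.random.Generator]:
    """Independent per-component substreams from one integer seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_covariate(
    T_cov: int,
    seed: int,
    start_year: int = 1997,
    level: float = 50_000.0,
    trend: float = -0.08,
    noise_sd: float = 0.35,
) -> CovariateSeries:
    """Simulate a positive annual biomass series with lognormal noise.

    ``trend`` is a per-year slope on the log scale (the default gives the
    gradual multi-year decline seen in Great Lakes zooplankton records).
    A constant series (trend and noise both zero) is rejected because its
    z-scores are undefined.
    """
    if T_cov < 2:
        raise DataValidationError("covariate needs >= 2 years for z-scoring")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    t = np.arange(T_cov)
    log_b = np.log(level) + trend * t + rng.normal(0.0, noise_sd, size=T_cov)
    return CovariateSeries(
        years=np.arange(start_year, start_year + T_cov), biomass=np.exp(log_b)
    )


def regime_of_transitions(config: SimulationConfig) -> np.ndarray:
    """Regime (1 or 2) of each year-transition, indexed by origin year."""
    origin = np.arange(config.start_year, config.end_year)
    return np.where(origin < config.covariate_start, 1, 2)


def growth_rate_means(
    config: SimulationConfig, covariate: CovariateSeries
) -> np.ndarray:
    """(S, T-1) regime-appropriate growth-rate means per species-transition."""
    origin = np.arange(config.start_year, config.end_year)
    regime = regime_of_transitions(config)
    S, Tm1 = len(config.species), origin.size
    means = np.empty((S, Tm1))
    for i, sp in enumerate(config.species):
        g = config.group_of(sp)
        for t, yr in enumerate(origin):
            if regime[t] == 1:
                means[i, t] = config.lambda_bar[g]
            else:
                means[i, t] = config.alpha[g] + config.beta[g] * covariate.zscore_of(yr)
    return means


def simulate_growth_rates(
    config: SimulationConfig, covariate: CovariateSeries, seed: int
) -> np.ndarray:
    """Draw λ_{s,t} ~ Normal(regime mean, σ_λ of the species' guild).

    With σ_λ = 0 the draws collapse exactly to the regime means.
    """
    rng = _rng_streams(seed, 4)[1]
    means = growth_rate_means(config, covariate)
    scales = np.array(
        [config.sigma_lam[config.group_of(sp)] for sp in config.species]
    )[:, None]
    return rng.normal(means, np.broadcast_to(scales, means.shape))


def simulate_latent_states(
    config: SimulationConfig, growth_rates: np.ndarray
) -> np.ndarray:
    """Deterministic log-abundance trajectories: n_{s,t+1} = n_{s,t} + λ_{s,t}."""
    n1 = np.array([config.n1[sp] for sp in config.species])
    increments = np.concatenate(
        [np.zeros((len(config.species), 1)), np.cumsum(growth_rates, axis=1)], axis=1
    )
    return n1[:, None] + increments


def _event_roster(config: SimulationConfig) -> list[tuple[int, int, str, int]]:
    """(year, month, site, event) tuples of every sampling event."""
    roster = []
    for era in config.eras:
        for year in range(era.start_year, era.end_year + 1):
            for month in era.months:
                for site in era.sites:
                    for ev in range(1, era.events_per_site_month + 1):
                        roster.append((year, month, site, ev))
    return roster


def simulate_observations(
    config: SimulationConfig,
    latent_states: np.ndarray,
    seed: int,
) -> tuple[list[SurveyObservation], dict[tuple[str, str], float], list[tuple]]:
    """Draw Poisson-lognormal counts for every event and species.

    Site effects γ ~ Normal(0, σ_γ,s) are drawn once per species-site pair;
    overdispersion ε ~ Normal(0, σ_ε,s) per event-species.  Counts are
    y ~ Poisson(exp(n_{s,t} + γ + ε)).  Events whose log mean exceeds the
    configured cap are flagged (and sampled at the cap) rather than silently
    truncated.
    """
    _, _, rng_gamma, rng_obs = _rng_streams(seed, 4)
    all_sites = sorted({s for e in config.eras for s in e.sites})
    gamma = {
        (sp, site): rng_gamma.normal(0.0, config.sigma_gamma[sp])
        for sp in config.species
        for site in all_sites
    }
    observations: list[SurveyObservation] = []
    overflow: list[tuple] = []
    for (year, month, site, ev) in _event_roster(config):
        t = year - config.start_year
        for i, sp in enumerate(config.species):
            eps = rng_obs.normal(0.0, config.sigma_eps[sp])
            log_mu = latent_states[i, t] + gamma[(sp, site)] + eps
            if log_mu > config.log_mu_cap:
                overflow.append((year, month, site, ev, sp))
                log_mu = config.log_mu_cap
            count = int(rng_obs.poisson(np.exp(log_mu)))
            observations.append(
                SurveyObservation(year, month, site, sp, count, effort=1.0, event=ev)
            )
    if overflow:
        warnings.warn(
            f"{len(overflow)} simulated events exceeded the log-mean cap "
            f"({config.log_mu_cap}) and were flagged", stacklevel=2,
        )
    # drop gamma entries for sites a species never co-occurred with (none here:
    # every site hosts every species in the roster) — keep all for the truth file
    return observations, gamma, overflow


def simulate_dataset(config: SimulationConfig | None = None,
                     seed: int = 0) -> SimulatedDataset:
    """Run the full forward simulation under one seed.

    Substreams are allocated per component (covariate, growth, site effects,
    counts) so that changing one block of the configuration does not perturb
    the draws of the others.
    """
    config = config or SimulationConfig()
    T_cov = config.end_year - config.covariate_start  # covariate ends at T-1
    covariate = simulate_covariate(
        T_cov, seed, start_year=config.covariate_start,
        level=config.covariate_level, trend=config.covariate_trend,
        noise_sd=config.covariate_noise_sd,
    )
    growth = simulate_growth_rates(config, covariate, seed)
    latent = simulate_latent_states(config, growth)
    obs, gamma, overflow = simulate_observations(config, latent, seed)
    return SimulatedDataset(
        config=config, observations=obs, covariate=covariate,
        latent_states=latent, growth_rates=growth, site_effects=gamma,
        overflow_events=overflow, seed=seed,
    )
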