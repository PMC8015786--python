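import numpy as np
import pytest

from guildgrowth import (
    CovariateSeries,
    Era,
    FunctionalGroupMap,
    SimulationConfig,
    StudyConfig,
    SurveyObservation,
    build_model_inputs,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def tiny_group_map() -> FunctionalGroupMap:
    return FunctionalGroupMap(
        {
            "ALE": "planktivore",
            "JOD": "benthic invertivore",
            "YEP": "general invertivore",
        }
    )


@pytest.fixture(scope="session")
def tiny_sim_config() -> SimulationConfig:
    """3 species / 8 years / 2-era roster: big enough to exercise every
    index path, small enough for oracle loops."""
    return SimulationConfig(
        group_map={
            "ALE": "planktivore",
            "JOD": "benthic invertivore",
            "YEP": "general invertivore",
        },
        eras=(
            Era(2000, 2003, ("M",), (7,), 2),
            Era(2004, 2007, ("M", "K"), (7,), 1),
        ),
        covariate_start=2004,
        lambda_bar={"planktivore": 0.1, "benthic invertivore": -0.1,
                    "general invertivore": 0.0},
        sigma_lam={"planktivore": 0.3, "benthic invertivore": 0.4,
                   "general invertivore": 0.2},
        alpha={"planktivore": 0.0, "benthic invertivore": 0.1,
               "general invertivore": -0.1},
        beta={"planktivore": 0.2, "benthic invertivore": -0.1,
              "general invertivore": 0.0},
        n1={"ALE": 3.0, "JOD": 1.0, "YEP": 2.0},
        sigma_eps=0.4,
        sigma_gamma=0.3,
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_sim_config):
    return simulate_dataset(tiny_sim_config, seed=42)


@pytest.fixture(scope="session")
def tiny_inputs(tiny_dataset):
    return tiny_dataset.to_model_inputs()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260101)


@pytest.fixture(scope="session")
def conjugate_setup():
    """One species, every block fixed except λ̄: the posterior is the
    closed-form normal-normal combination of the regime-1 growth draws."""
    cfg = SimulationConfig(
        group_map={"A": "planktivore"},
        eras=(Era(2000, 2009, ("X",), (7,), 1),),
        covariate_start=2007,
        lambda_bar={"planktivore": 0.3},
        sigma_lam={"planktivore": 0.4},
        alpha={"planktivore": 0.0}, beta={"planktivore": 0.0},
        n1={"A": 2.0}, sigma_eps=0.0, sigma_gamma=0.0,
    )
    ds = simulate_dataset(cfg, seed=7)
    ins = ds.to_model_inputs()
    fixed = {
        "lam": ds.growth_rates, "n1": np.array([2.0]),
        "alpha": np.array([0.0]), "beta": np.array([0.0]),
        "sigma_lam": np.array([0.4]),
        "gamma": np.zeros(ins.n_site_effects), "sigma_gamma": np.zeros(1),
        "eps": np.zeros(ins.n_obs), "sigma_eps": np.zeros(1),
    }
    lam1 = ds.growth_rates[:, ins.regime == 1].ravel()
    prec = 1 / 4 + lam1.size / 0.4**2
    post_mean = (lam1.sum() / 0.4**2) / prec
    post_sd = float(np.sqrt(1 / prec))
    return ins, fixed, float(post_mean), post_sd


def make_observations(rows):
    """rows of (year, month, site, species, count[, effort[, event]])."""
    return [SurveyObservation(*r) for r in rows]


@pytest.fixture(scope="session")
def two_year_inputs(tiny_group_map):
    """Minimal hand-built inputs: 1 species equivalent per row checks."""
    obs = [
        SurveyObservation(2000, 7, "M", "ALE", 5),
        SurveyObservation(2000, 7, "M", "JOD", 1),
        SurveyObservation(2000, 7, "M", "YEP", 2),
        SurveyObservation(2001, 7, "M", "ALE", 7),
        SurveyObservation(2001, 7, "M", "JOD", 0),
        SurveyObservation(2001, 7, "M", "YEP", 3),
    ]
    cov = CovariateSeries(years=[1999, 2000], biomass=[10.0, 30.0])
    return build_model_inputs(obs, cov, tiny_group_map,
                              StudyConfig(2000, 2001))
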