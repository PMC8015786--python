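"""Survey and covariate ingestion, CPUE summaries, and model-input assembly.

The survey table is long-format trawl data: one row per sampling event and
species, with the number of fish captured and the trawl effort in hours.
The covariate table is an annual total zooplankton dry-weight biomass series
(μgDW/m³).  Both arrive as delimited text (CSV/TSV); column names are
configurable.

Catch per unit effort (CPUE) is total catch per hour of trawl sampling.
Annual CPUE pools all sites and months within a year: (total count in the
year) / (total effort hours in the year).  A species not recorded in a
sampled year contributes a zero catch for that year, not missing data.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("guildgrowth")

GROUP_LABELS = ("benthic invertivore", "general invertivore", "planktivore")

#: default column-name resolution for delimited input tables
DEFAULT_SURVEY_COLUMNS = {
    "year": "year",
    "month": "month",
    "site": "site",
    "species": "species",
    "count": "count",
    "effort": "effort",
    "event": "event",
}
DEFAULT_COVARIATE_COLUMNS = {"year": "year", "biomass": "biomass"}


class ConfigurationError(ValueError):
    """A config/column problem: the input cannot even be interpreted."""


class DataValidationError(ValueError):
    """Interpreted input violates an invariant (negative count, year gap...)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SurveyObservation:
    """One trawl event's count for one species.

    ``event`` disambiguates repeated sampling of the same site within a
    month (the survey visited each site twice monthly in the dense era).
    """

    year: int
    month: int
    site: str
    species: str
    count: int
    effort: float = 1.0
    event: int = 1

    def __post_init__(self) -> None:
        if self.count < 0 or int(self.count) != self.count:
            raise DataValidationError(
                f"count must be a non-negative integer, got {self.count!r}"
            )
        if not self.effort > 0:
            raise DataValidationError(f"effort must be > 0, got {self.effort!r}")
        if not 1 <= self.month <= 12:
            raise DataValidationError(f"month must be in 1..12, got {self.month!r}")


class FunctionalGroupMap:
    """Species → functional feeding group (guild) assignment.

    Groups partition the species set; every species maps to exactly one of
    the three guilds (benthic invertivore, general invertivore, planktivore).
    """

    def __init__(self, mapping: dict[str, str]):
        bad = {g for g in mapping.values() if g not in GROUP_LABELS}
        if bad:
            raise ConfigurationError(
                f"unknown functional group label(s) {sorted(bad)}; "
                f"expected one of {GROUP_LABELS}"
            )
        if not mapping:
            raise ConfigurationError("group map is empty")
        self._map = dict(mapping)

    def __getitem__(self, species: str) -> str:
        return self._map[species]

    def __contains__(self, species: str) -> bool:
        return species in self._map

    def __len__(self) -> int:
        return len(self._map)

    @property
    def species(self) -> list[str]:
        return sorted(self._map)

    @property
    def groups(self) -> list[str]:
        """Group labels present, in canonical guild order."""
        present = set(self._map.values())
        return [g for g in GROUP_LABELS if g in present]

    def items(self):
        return self._map.items()


@dataclass
class CovariateSeries:
    """Annual covariate (zooplankton biomass) with its z-score standardization.

    z-scores use the sample standard deviation (n−1 divisor) and have mean 0
    and unit SD over the covariate years.
    """

    years: np.ndarray
    biomass: np.ndarray
    mean: float = field(init=False)
    sd: float = field(init=False)
    z: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.biomass = np.asarray(self.biomass, dtype=float)
        if self.years.size != self.biomass.size:
            raise DataValidationError("years and biomass differ in length")
        if self.years.size < 2:
            raise DataValidationError("covariate series needs at least 2 years")
        if np.any(np.diff(self.years) != 1):
            raise DataValidationError(
                f"covariate years must be contiguous, got {self.years.tolist()}"
            )
        if np.any(self.biomass < 0):
            raise DataValidationError("biomass must be non-negative")
        self.mean = float(np.mean(self.biomass))
        self.sd = float(np.std(self.biomass, ddof=1))
        if self.sd == 0.0:
            raise DataValidationError(
                "covariate series has zero variance; z-scores are undefined"
            )
        self.z = (self.biomass - self.mean) / self.sd

    def zscore_of(self, year: int) -> float:
        idx = np.flatnonzero(self.years == year)
        if idx.size == 0:
            raise KeyError(f"no covariate value for year {year}")
        return float(self.z[idx[0]])


@dataclass
class StudyConfig:
    """Configured study span (calendar years, inclusive)."""

    start_year: int
    end_year: int

    def __post_init__(self) -> None:
        if self.end_year <= self.start_year:
            raise ConfigurationError("end_year must exceed start_year")

    @property
    def n_years(self) -> int:
        return self.end_year - self.start_year + 1


@dataclass
class ModelInputs:
    """Flat index arrays consumed by the state-space model.

    One observation row per (event, species): the event roster is crossed
    with the species list so that zero catches are explicit Poisson data.
    ``regime`` marks each year-transition t→t+1 (indexed by origin year):
    1 = growth mean is the guild mean, 2 = growth mean is the guild
    covariate regression; ``x`` holds the covariate z-score for regime-2
    transitions (0.0 placeholder elsewhere).
    """

    count: np.ndarray          # (N,) int
    species_idx: np.ndarray    # (N,) int in [0, S)
    year_idx: np.ndarray       # (N,) int in [0, T)
    gamma_idx: np.ndarray      # (N,) int in [0, G): species-site effect slot
    gamma_species: np.ndarray  # (G,) owning species of each site-effect slot
    gamma_site: list[str]      # (G,) site code of each slot
    species: list[str]         # (S,) species codes
    group_labels: list[str]    # (F,) guild labels
    group_idx: np.ndarray      # (S,) int in [0, F)
    years: np.ndarray          # (T,) calendar years
    regime: np.ndarray         # (T-1,) int in {1, 2}
    x: np.ndarray              # (T-1,) covariate z-score per transition
    covariate_mean: float
    covariate_sd: float
    source_row: np.ndarray | None = None  # (n_obs,) row index of each input obs

    @property
    def n_obs(self) -> int:
        return self.count.size

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_groups(self) -> int:
        return len(self.group_labels)

    @property
    def n_years(self) -> int:
        return self.years.size

    @property
    def n_site_effects(self) -> int:
        return len(self.gamma_site)

    def validate(self) -> None:
        if self.count.min(initial=0) < 0:
            raise DataValidationError("negative count in model inputs")
        for name, arr, hi in [
            ("species_idx", self.species_idx, self.n_species),
            ("year_idx", self.year_idx, self.n_years),
            ("gamma_idx", self.gamma_idx, self.n_site_effects),
        ]:
            if arr.size and (arr.min() < 0 or arr.max() >= hi):
                raise DataValidationError(f"{name} out of range [0, {hi})")
        if self.regime.size != self.n_years - 1:
            raise DataValidationError("regime must have one entry per transition")
        if not np.all(np.isin(self.regime, (1, 2))):
            raise DataValidationError("regime entries must be 1 or 2")
        if np.any(~np.isfinite(self.x[self.regime == 2])):
            raise DataValidationError("missing covariate for a regime-2 transition")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _read_table(path, columns: dict[str, str], required: list[str], kind: str):
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [k for k in required if columns[k] not in df.columns]
    if missing:
        raise ConfigurationError(
            f"{kind} file {path} lacks column(s) "
            + ", ".join(f"{columns[k]!r} (for {k})" for k in missing)
        )
    return df


def read_survey(
    path,
    group_map: FunctionalGroupMap | None = None,
    columns: dict[str, str] | None = None,
    default_effort: float = 1.0,
    study: StudyConfig | None = None,
) -> list[SurveyObservation]:
    """Read a long-format trawl survey table.

    The effort column is optional; absent, each event defaults to
    ``default_effort`` hours (the survey protocol trawled 1 h per event).
    Rows whose species is missing from ``group_map`` are rejected with an
    error listing the offending codes.
    """
    cols = {**DEFAULT_SURVEY_COLUMNS, **(columns or {})}
    df = _read_table(path, cols, ["year", "month", "site", "species", "count"], "survey")
    if df.empty:
        warnings.warn(f"survey file {path} has no data rows", stacklevel=2)
        return []
    if cols["effort"] not in df.columns:
        df[cols["effort"]] = default_effort
    if cols["event"] not in df.columns:
        df[cols["event"]] = 1

    counts = pd.to_numeric(df[cols["count"]], errors="raise")
    bad = np.flatnonzero(counts.to_numpy() < 0)
    if bad.size:
        raise DataValidationError(
            f"negative count at data row(s) {[int(b) + 2 for b in bad[:5]]} of {path}"
        )
    if group_map is not None:
        unknown = sorted(set(df[cols["species"]].astype(str)) - set(group_map.species))
        if unknown:
            raise DataValidationError(
                f"species not in the functional group map: {unknown}"
            )
    if study is not None:
        yrs = df[cols["year"]].astype(int)
        out = sorted(set(yrs[(yrs < study.start_year) | (yrs > study.end_year)]))
        if out:
            raise DataValidationError(
                f"survey year(s) {out} outside configured span "
                f"{study.start_year}-{study.end_year}"
            )

    obs = [
        SurveyObservation(
            year=int(r[cols["year"]]),
            month=int(r[cols["month"]]),
            site=str(r[cols["site"]]),
            species=str(r[cols["species"]]),
            count=int(r[cols["count"]]),
            effort=float(r[cols["effort"]]),
            event=int(r[cols["event"]]),
        )
        for r in df.to_dict("records")
    ]
    logger.info("read %d survey rows from %s", len(obs), path)
    return obs


def read_covariate(path, columns: dict[str, str] | None = None) -> CovariateSeries:
    """Read the annual covariate table and attach z-scores (n−1 divisor)."""
    cols = {**DEFAULT_COVARIATE_COLUMNS, **(columns or {})}
    df = _read_table(path, cols, ["year", "biomass"], "covariate")
    try:
        biomass = pd.to_numeric(df[cols["biomass"]], errors="raise").to_numpy(float)
    except (ValueError, TypeError) as exc:
        raise DataValidationError(f"non-numeric biomass in {path}: {exc}") from exc
    order = np.argsort(df[cols["year"]].to_numpy())
    series = CovariateSeries(
        years=df[cols["year"]].to_numpy(int)[order], biomass=biomass[order]
    )
    logger.info(
        "covariate %d-%d: mean %.0f, sd %.0f",
        series.years[0], series.years[-1], series.mean, series.sd,
    )
    return series


# ---------------------------------------------------------------------------
# descriptive statistics
# ---------------------------------------------------------------------------


def _observations_frame(observations: list[SurveyObservation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "year": [o.year for o in observations],
            "month": [o.month for o in observations],
            "site": [o.site for o in observations],
            "species": [o.species for o in observations],
            "count": [o.count for o in observations],
            "effort": [o.effort for o in observations],
            "event": [o.event for o in observations],
        }
    )


def annual_cpue(observations: list[SurveyObservation]) -> pd.DataFrame:
    """Annual CPUE per species, pooling all sites and months within a year.

    Annual effort is summed over distinct sampling events (year, month,
    site, event), so listing several species for one event does not double
    count its trawl hours.  Species with no row in a sampled year get CPUE 0.
    """
    if not observations:
        raise DataValidationError("no observations")
    df = _observations_frame(observations)
    effort = (
        df.drop_duplicates(["year", "month", "site", "event"])
        .groupby("year")["effort"]
        .sum()
    )
    catch = (
        df.groupby(["species", "year"])["count"]
        .sum()
        .unstack("year", fill_value=0)
        .reindex(columns=effort.index, fill_value=0)
    )
    cpue = catch.div(effort, axis=1)
    return cpue  # rows species, columns year


def summarize_cpue(
    observations: list[SurveyObservation],
    group_map: FunctionalGroupMap | None = None,
) -> pd.DataFrame:
    """Per-species summary of annual CPUE: mean, sample SD, Q1, Q3, maximum.

    Quartiles use linear interpolation between order statistics.  Returns a
    DataFrame with columns species, group, mean, sd, q1, q3, max.
    """
    cpue = annual_cpue(observations)
    rows = []
    for species, vals in cpue.iterrows():
        v = vals.to_numpy(float)
        if v.size == 0:
            warnings.warn(f"species {species} has no sampled years; excluded",
                          stacklevel=2)
            continue
        rows.append(
            {
                "species": species,
                "group": group_map[species] if group_map else "",
                "mean": float(np.mean(v)),
                "sd": float(np.std(v, ddof=1)) if v.size > 1 else 0.0,
                "q1": float(np.quantile(v, 0.25)),
                "q3": float(np.quantile(v, 0.75)),
                "max": float(np.max(v)),
            }
        )
    out = pd.DataFrame(rows)
    if group_map is not None and not out.empty:
        order = {g: i for i, g in enumerate(GROUP_LABELS)}
        out = out.sort_values(
            ["group", "species"], key=lambda s: s.map(order).fillna(s)
        ).reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# model input assembly
# ---------------------------------------------------------------------------


def build_model_inputs(
    observations: list[SurveyObservation],
    covariate: CovariateSeries,
    group_map: FunctionalGroupMap,
    study: StudyConfig,
) -> ModelInputs:
    """Assemble dense 0-based index arrays for the state-space model.

    The event roster (distinct year/month/site/event tuples) is crossed with
    the full species list so absent species become explicit zero counts.
    Year-transitions originating before the covariate record are regime 1;
    transitions originating in covariate years are regime 2 and carry the
    origin year's covariate z-score.
    """
    if not observations:
        raise DataValidationError("no observations")
    unknown = sorted({o.species for o in observations} - set(group_map.species))
    if unknown:
        raise DataValidationError(f"species not in the functional group map: {unknown}")
    df = _observations_frame(observations)
    out_of_span = sorted(
        set(df.year[(df.year < study.start_year) | (df.year > study.end_year)])
    )
    if out_of_span:
        raise DataValidationError(
            f"survey year(s) {out_of_span} outside configured span"
        )
    if covariate.years[-1] > study.end_year:
        raise DataValidationError(
            f"covariate extends to {covariate.years[-1]}, beyond the survey span"
        )
    if covariate.years[-1] < study.end_year - 1:
        raise DataValidationError(
            "covariate must extend through the penultimate survey year "
            f"({study.end_year - 1}); it ends at {covariate.years[-1]}"
        )

    species = group_map.species
    groups = group_map.groups
    sp_of = {s: i for i, s in enumerate(species)}
    gr_of = {g: i for i, g in enumerate(groups)}
    group_idx = np.array([gr_of[group_map[s]] for s in species])

    events = df.drop_duplicates(["year", "month", "site", "event"])[
        ["year", "month", "site", "event"]
    ].reset_index(drop=True)
    # cross events with species; merge back observed counts (absent -> 0)
    full = events.merge(pd.DataFrame({"species": species}), how="cross")
    obs_counts = (
        df.groupby(["year", "month", "site", "event", "species"], as_index=False)[
            "count"
        ].sum()
    )
    full = full.merge(
        obs_counts, on=["year", "month", "site", "event", "species"], how="left"
    )
    full["count"] = full["count"].fillna(0).astype(int)

    # species-site random-effect slots: every (species, site) pair with events
    site_pairs = (
        full[["species", "site"]].drop_duplicates().sort_values(["species", "site"])
    )
    gamma_key = {
        (r.species, r.site): i for i, r in enumerate(site_pairs.itertuples())
    }

    years = np.arange(study.start_year, study.end_year + 1)
    origin = years[:-1]
    regime = np.where(origin < covariate.years[0], 1, 2)
    x = np.zeros(origin.size)
    for i, yr in enumerate(origin):
        if regime[i] == 2:
            x[i] = covariate.zscore_of(int(yr))

    inputs = ModelInputs(
        count=full["count"].to_numpy(int),
        species_idx=full["species"].map(sp_of).to_numpy(int),
        year_idx=(full["year"] - study.start_year).to_numpy(int),
        gamma_idx=np.array(
            [gamma_key[(s, st)] for s, st in zip(full["species"], full["site"])]
        ),
        gamma_species=np.array([sp_of[r.species] for r in site_pairs.itertuples()]),
        gamma_site=[r.site for r in site_pairs.itertuples()],
        species=species,
        group_labels=groups,
        group_idx=group_idx,
        years=years,
        regime=regime,
        x=x,
        covariate_mean=covariate.mean,
        covariate_sd=covariate.sd,
    )

    # map every input observation to its (unique) model row
    key_cols = ["year", "month", "site", "event", "species"]
    row_of = {
        tuple(t): i
        for i, t in enumerate(full[key_cols].itertuples(index=False, name=None))
    }
    inputs.source_row = np.array(
        [row_of[(o.year, o.month, o.site, o.event, o.species)] for o in observations]
    )
    inputs.validate()
    logger.info(
        "model inputs: %d rows, %d species, %d groups, %d years, %d site effects",
        inputs.n_obs, inputs.n_species, inputs.n_groups, inputs.n_years,
        inputs.n_site_effects,
    )
    return inputs


# ---------------------------------------------------------------------------
# config files
# ---------------------------------------------------------------------------


def load_config(path) -> dict:
    """Load a YAML config file (blocks: data | simulation, model, mcmc, output)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigurationError(f"config {path} must be a mapping")
    return cfg


def group_map_from_config(cfg: dict) -> FunctionalGroupMap:
    try:
        return FunctionalGroupMap(dict(cfg["groups"]))
    except KeyError as exc:
        raise ConfigurationError("config lacks a 'groups' block") from exc
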