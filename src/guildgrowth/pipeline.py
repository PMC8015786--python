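"""End-to-end orchestration: simulate/load → fit → summarize → derived tables,
plus the simulate-fit-recover study used to validate the inference.

A run is driven by a single YAML config with blocks ``data`` *or*
``simulation``, ``mcmc``, and (for real data) ``groups``; every run
directory receives a JSON manifest recording the config hash, seed, input
checksums and backend, so reruns are reproducible and auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import data_io, results
from .data_io import (
    ConfigurationError,
    FunctionalGroupMap,
    StudyConfig,
    load_config,
)
from .diagnostics import check_convergence, summarize
from .model import BACKEND_ID, MCMCConfig, PosteriorDraws, fit
from .synthetic import Era, SimulatedDataset, SimulationConfig, simulate_dataset

logger = logging.getLogger("guildgrowth")


class StageError(RuntimeError):
    """A pipeline stage failed; names the stage and keeps the cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    backend: str
    input_checksums: dict[str, str]
    started: str
    finished: str = ""
    outputs: list[str] = field(default_factory=list)

    def write(self, out_dir) -> Path:
        path = Path(out_dir) / "manifest.json"
        path.write_text(json.dumps(self.__dict__, indent=2))
        return path


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()


# ---------------------------------------------------------------------------
# config handling
# ---------------------------------------------------------------------------


def simulation_config_from_dict(d: dict) -> SimulationConfig:
    """Build a SimulationConfig from a (possibly partial) config mapping."""
    kwargs = dict(d or {})
    if "eras" in kwargs:
        kwargs["eras"] = tuple(
            Era(
                start_year=int(e["start_year"]),
                end_year=int(e["end_year"]),
                sites=tuple(e["sites"]),
                months=tuple(e.get("months", (7,))),
                events_per_site_month=int(e.get("events_per_site_month", 1)),
            )
            for e in kwargs["eras"]
        )
    return SimulationConfig(**kwargs)


def mcmc_config_from_dict(d: dict | None) -> tuple[MCMCConfig, bool]:
    d = dict(d or {})
    shared = bool(d.pop("shared_obs_sigmas", False))
    return MCMCConfig(**d), shared


def _resolve_config(config) -> dict:
    if isinstance(config, (str, Path)):
        return load_config(config)
    if isinstance(config, dict):
        return config
    raise ConfigurationError("config must be a path or a mapping")


# ---------------------------------------------------------------------------
# the pipeline
# ---------------------------------------------------------------------------


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage=%s status=start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is not None:
                logger.error("stage=%s status=failed wall=%.1fs: %s",
                             name, dt, exc)
                raise StageError(name, exc) from exc
            logger.info("stage=%s status=done wall=%.1fs", name, dt)
            return False

    return _Ctx()


def run_pipeline(
    config,
    seed: int = 0,
    out_dir="runs/latest",
    allow_unconverged: bool = False,
) -> RunManifest:
    """Execute the full analysis and write every canonical output.

    Outputs: the (simulated or copied-reference) input tables, the CPUE
    summary, saved draws, the parameter summary with convergence report,
    the five derived tables, and a run manifest.  Fails loudly if the
    convergence check fails, unless ``allow_unconverged``.
    """
    cfg = _resolve_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=_config_hash(cfg), seed=seed, backend=BACKEND_ID,
        input_checksums={},
        started=datetime.now(timezone.utc).isoformat(),
    )

    with _stage("data"):
        if "simulation" in cfg:
            sim_cfg = simulation_config_from_dict(cfg["simulation"])
            dataset = simulate_dataset(sim_cfg, seed=seed)
            write_dataset(dataset, out)
            observations = dataset.observations
            covariate = dataset.covariate
            group_map = sim_cfg.functional_groups
            study = sim_cfg.study
            for f in ("survey.csv", "covariate.csv"):
                manifest.input_checksums[f] = _sha256(out / f)
        elif "data" in cfg:
            dcfg = cfg["data"]
            group_map = data_io.group_map_from_config(cfg)
            study = StudyConfig(**dcfg["study"])
            cols = dcfg.get("columns", {})
            observations = data_io.read_survey(
                dcfg["survey"], group_map=group_map,
                columns=cols.get("survey"), study=study,
            )
            covariate = data_io.read_covariate(
                dcfg["covariate"], columns=cols.get("covariate")
            )
            for key in ("survey", "covariate"):
                manifest.input_checksums[key] = _sha256(dcfg[key])
        else:
            raise ConfigurationError(
                "config needs a 'simulation' or 'data' block"
            )

    with _stage("model_inputs"):
        inputs = data_io.build_model_inputs(observations, covariate,
                                            group_map, study)
        cpue = data_io.summarize_cpue(observations, group_map)
        cpue.to_csv(out / "cpue_summary.csv", index=False)

    with _stage("fit"):
        mcmc, shared = mcmc_config_from_dict(cfg.get("mcmc"))
        draws = fit(inputs, mcmc, seed=seed, shared_obs_sigmas=shared)
        draws.save(out / "draws")

    with _stage("summarize"):
        summary = summarize(draws)
        summary.to_csv(out / "summary.csv", index=False)
        report = check_convergence(summary)
        (out / "convergence.txt").write_text(str(report) + "\n")
        if not report.passed and not allow_unconverged:
            raise RuntimeError(str(report))

    with _stage("derived"):
        paths = results.write_derived_tables(draws, out / "derived")
        manifest.outputs = sorted(
            str(p.relative_to(out)) for p in out.rglob("*") if p.is_file()
        )

    manifest.finished = datetime.now(timezone.utc).isoformat()
    manifest.write(out)
    return manifest


def write_dataset(dataset: SimulatedDataset, out_dir) -> None:
    """Persist a simulated dataset: survey CSV, covariate CSV, truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    obs = dataset.observations
    pd.DataFrame(
        {
            "year": [o.year for o in obs],
            "month": [o.month for o in obs],
            "site": [o.site for o in obs],
            "species": [o.species for o in obs],
            "count": [o.count for o in obs],
            "effort": [o.effort for o in obs],
            "event": [o.event for o in obs],
        }
    ).to_csv(out / "survey.csv", index=False)
    pd.DataFrame(
        {"year": dataset.covariate.years, "biomass": dataset.covariate.biomass}
    ).to_csv(out / "covariate.csv", index=False)
    (out / "truth.json").write_text(json.dumps(dataset.truth_dict(), indent=2))


# ---------------------------------------------------------------------------
# parameter-recovery study
# ---------------------------------------------------------------------------

GROUP_LEVEL_BLOCKS = ("lambda_bar", "sigma_lam", "alpha", "beta")


@dataclass
class RecoveryReport:
    """Per-replicate CRI records and the aggregated coverage table."""

    records: pd.DataFrame   # replicate, parameter, truth, median, CRI, covered
    coverage: pd.DataFrame  # parameter, coverage, mean_bias, n

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.records.to_csv(out / "recovery_records.csv", index=False)
        self.coverage.to_csv(out / "recovery_coverage.csv", index=False)


def run_recovery_study(
    config,
    replicates: int,
    seed: int = 0,
    out_dir=None,
) -> RecoveryReport:
    """Repeated simulate→fit cycles scoring 95% CRI coverage of the
    group-level parameters (λ̄_f, σ_λ,f, α_f, β_f) and their bias."""
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    cfg = _resolve_config(config)
    sim_cfg = simulation_config_from_dict(cfg.get("simulation", {}))
    mcmc, shared = mcmc_config_from_dict(cfg.get("mcmc"))
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31 - 1, size=(replicates, 2))

    truth = {}
    for block, by_group in (
        ("lambda_bar", sim_cfg.lambda_bar), ("sigma_lam", sim_cfg.sigma_lam),
        ("alpha", sim_cfg.alpha), ("beta", sim_cfg.beta),
    ):
        for g, v in by_group.items():
            truth[f"{block}[{g}]"] = float(v)

    records = []
    for r in range(replicates):
        with _stage(f"recovery replicate {r}"):
            dataset = simulate_dataset(sim_cfg, seed=int(rep_seeds[r, 0]))
            inputs = dataset.to_model_inputs()
            draws = fit(inputs, mcmc, seed=int(rep_seeds[r, 1]),
                        shared_obs_sigmas=shared)
            summary = summarize(draws, blocks=list(GROUP_LEVEL_BLOCKS))
            for row in summary.itertuples():
                if row.parameter not in truth:
                    continue
                tv = truth[row.parameter]
                records.append(
                    {
                        "replicate": r,
                        "parameter": row.parameter,
                        "truth": tv,
                        "median": row.median,
                        "lower95": row.lower95,
                        "upper95": row.upper95,
                        "covered": bool(row.lower95 <= tv <= row.upper95),
                        "bias": row.median - tv,
                    }
                )
    rec = pd.DataFrame(records)
    coverage = (
        rec.groupby("parameter")
        .agg(coverage=("covered", "mean"), mean_bias=("bias", "mean"),
             n=("covered", "size"))
        .reset_index()
    )
    report = RecoveryReport(records=rec, coverage=coverage)
    if out_dir is not None:
        report.write(out_dir)
    return report
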