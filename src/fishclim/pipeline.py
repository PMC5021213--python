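"""End-to-end orchestration: one config, one seed, one artifact tree.

Stage order: synthetic data (demo mode) → climate preparation → growth-core
fitting → distribution-climate ensemble → growth-climate ensemble →
range statistics → integration. Every stage's outputs are written before the
next stage starts (when an output directory is configured), and all
randomness derives from the single root seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._rng import derive_rng, derive_seed
from .climate_prep import DEFAULT_CORRELATION_THRESHOLD, reduce_variables
from .exceptions import ConfigError
from .grid import CORE_VARIABLES, ClimateGrid, ScenarioSpec, apply_scenario, write_climate_csv
from .growth import fit_populations
from .growth_climate import fit_growth_ensemble, project_growth
from .integration import (
    build_growth_curves,
    fit_coupling_regression,
    scenario_report,
)
from .range_stats import scenario_range_summary
from .sdm import (
    ALGORITHM_IDS,
    DEFAULT_AUC_CUTOFF,
    DEFAULT_N_REPS,
    DEFAULT_PRESENCE_THRESHOLD,
    DEFAULT_TRAIN_FRAC,
    fit_sdm_ensemble,
    predict_presence,
)
from .synthetic import (
    GrowthResponseSpec,
    NicheSpec,
    generate_climate_grid,
    generate_growth_data,
    generate_occurrences,
)

log = logging.getLogger(__name__)


@dataclass
class SyntheticBlock:
    """Generator settings for demo mode (the synthetic study system)."""

    n_lon: int = 24
    n_lat: int = 30
    species: str = "synthetic_cyprinid"
    niche_intercept: float = -12.0
    niche_coefficients: dict = field(
        default_factory=lambda: {"annual_mean_temp": 1.2}
    )
    prevalence_target: float = 0.35
    n_populations: int = 40
    n_fish_per_pop: int = 50
    max_age: int = 10
    growth_response: dict = field(
        default_factory=lambda: {
            "Linf_intercept": 420.0,
            "Linf_temp_slope": -12.0,
            "K_intercept": 0.06,
            "K_temp_slope": 0.02,
            "sd_Linf": 18.0,
            "sd_K": 0.025,
            "length_cv": 0.05,
            "scale_intercept": 0.5,
            "scale_slope": 0.01,
            "scale_sd": 0.08,
        }
    )


def default_scenarios() -> list[ScenarioSpec]:
    """Eight projections: two climate models × two emission pathways × two years.

    Warming magnitudes follow the usual low-emission (≈ +1 °C, stabilising)
    vs high-emission (≈ +2 to +3.7 °C by 2070) pattern, with the second
    model slightly warmer; high-emission scenarios also dry slightly.
    """
    rows = [
        ("modelA_low_2050", 1.0, 1.02, "2050"),
        ("modelA_high_2050", 2.0, 0.98, "2050"),
        ("modelA_low_2070", 1.1, 1.03, "2070"),
        ("modelA_high_2070", 3.0, 0.95, "2070"),
        ("modelB_low_2050", 1.3, 1.02, "2050"),
        ("modelB_high_2050", 2.4, 0.97, "2050"),
        ("modelB_low_2070", 1.4, 1.03, "2070"),
        ("modelB_high_2070", 3.7, 0.93, "2070"),
    ]
    return [ScenarioSpec(n, d, p, y) for n, d, p, y in rows]


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    seed: int
    outdir: str | None = None
    synthetic: SyntheticBlock = field(default_factory=SyntheticBlock)
    scenarios: list[ScenarioSpec] = field(default_factory=default_scenarios)
    candidate_variables: list[str] | None = None
    correlation_threshold: float = DEFAULT_CORRELATION_THRESHOLD
    algorithms: tuple = ALGORITHM_IDS
    n_reps: int = DEFAULT_N_REPS
    train_frac: float = DEFAULT_TRAIN_FRAC
    auc_cutoff: float = DEFAULT_AUC_CUTOFF
    presence_threshold: float = DEFAULT_PRESENCE_THRESHOLD
    growth_families: tuple = ("GLM", "GAM", "MARS")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["scenarios"] = [dataclasses.asdict(s) for s in self.scenarios]
        d["algorithms"] = list(self.algorithms)
        d["growth_families"] = list(self.growth_families)
        return d


_KNOWN_KEYS = {
    "seed",
    "outdir",
    "synthetic",
    "scenarios",
    "candidate_variables",
    "correlation_threshold",
    "algorithms",
    "n_reps",
    "train_frac",
    "auc_cutoff",
    "presence_threshold",
    "growth_families",
}


def validate_config(raw) -> RunConfig:
    """Parse and validate a raw config (YAML text, dict, or RunConfig).

    Defaults are injected for every omitted field (0.70 correlation
    threshold, AUC cutoff 0.7, presence threshold 0.6, 50 repetitions, 80:20
    split). Violations are collected and raised together as
    :class:`~fishclim.exceptions.ConfigError`; unknown fields warn only.
    """
    if isinstance(raw, RunConfig):
        data = raw.to_dict()
    elif isinstance(raw, str):
        data = yaml.safe_load(raw) or {}
    elif isinstance(raw, dict):
        data = dict(raw)
    else:
        raise ConfigError(["config: expected YAML text or mapping"])

    errors: list[str] = []
    unknown = set(data) - _KNOWN_KEYS
    for key in sorted(unknown):
        warnings.warn(f"unknown config field {key!r} ignored", stacklevel=2)
        data.pop(key)

    if "seed" not in data or data["seed"] is None:
        errors.append("seed: required")
    else:
        try:
            data["seed"] = int(data["seed"])
        except (TypeError, ValueError):
            errors.append("seed: must be an integer")

    for name in ("auc_cutoff", "presence_threshold", "train_frac"):
        if name in data:
            try:
                val = float(data[name])
            except (TypeError, ValueError):
                errors.append(f"{name}: must be a number")
                continue
            if not (0.0 < val < 1.0):
                errors.append(f"{name}: must lie in (0, 1), got {val}")
            data[name] = val
    if "correlation_threshold" in data:
        val = float(data["correlation_threshold"])
        if not (0.0 < val <= 1.0):
            errors.append(f"correlation_threshold: must lie in (0, 1], got {val}")
        data["correlation_threshold"] = val
    if "n_reps" in data:
        try:
            data["n_reps"] = int(data["n_reps"])
        except (TypeError, ValueError):
            errors.append("n_reps: must be an integer")
        else:
            if data["n_reps"] < 1:
                errors.append("n_reps: must be >= 1")

    if "synthetic" in data and not isinstance(data["synthetic"], SyntheticBlock):
        try:
            data["synthetic"] = SyntheticBlock(**(data["synthetic"] or {}))
        except TypeError as exc:
            errors.append(f"synthetic: {exc}")
    if "scenarios" in data and data["scenarios"] is not None:
        specs = []
        names = set()
        for i, entry in enumerate(data["scenarios"]):
            if isinstance(entry, ScenarioSpec):
                spec = entry
            else:
                try:
                    spec = ScenarioSpec(**entry)
                except Exception as exc:
                    errors.append(f"scenarios[{i}]: {exc}")
                    continue
            if spec.name in names:
                errors.append(f"scenarios[{i}].name: duplicate {spec.name!r}")
            names.add(spec.name)
            specs.append(spec)
        data["scenarios"] = specs
    if "algorithms" in data:
        bad = [a for a in data["algorithms"] if a not in ALGORITHM_IDS]
        if bad:
            errors.append(f"algorithms: unknown ids {bad}")
        data["algorithms"] = tuple(data["algorithms"])
    if "growth_families" in data:
        data["growth_families"] = tuple(data["growth_families"])

    if errors:
        raise ConfigError(errors)
    return RunConfig(**data)


def demo_config(seed: int, outdir: str | None = None, **overrides) -> RunConfig:
    """The default synthetic demonstration configuration."""
    cfg = RunConfig(seed=seed, outdir=outdir)
    if overrides:
        data = cfg.to_dict()
        data.update(overrides)
        cfg = validate_config(data)
    return cfg


@dataclass
class RunResult:
    """In-memory artifact tree of one pipeline run."""

    config: RunConfig
    baseline_grid: ClimateGrid
    scenario_grids: dict
    retained_variables: list[str]
    occurrences: object
    growth_params: pd.DataFrame
    sdm: object
    presence: dict
    growth_ensembles: dict
    projections: dict
    range_table: pd.DataFrame
    growth_means: pd.DataFrame
    coupling: dict
    curves: list
    report: dict
    timings: dict


def _config_hash(cfg: RunConfig) -> str:
    data = cfg.to_dict()
    data.pop("outdir", None)  # artifact location is not an analysis setting
    blob = json.dumps(data, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> RunResult:
    """Execute the full coupled range/growth analysis from one config."""
    cfg = validate_config(cfg)
    outdir = Path(cfg.outdir) if cfg.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    seed = cfg.seed
    syn = cfg.synthetic

    def stage(name):
        log.info("stage %s ...", name)
        return time.perf_counter()

    # -- synthetic data --------------------------------------------------
    t0 = stage("synthetic_data")
    baseline = generate_climate_grid(syn.n_lon, syn.n_lat, seed=derive_seed(seed, "grid"))
    scenario_grids = {s.name: apply_scenario(baseline, s) for s in cfg.scenarios}
    niche = NicheSpec(
        intercept=syn.niche_intercept,
        coefficients=syn.niche_coefficients,
        prevalence_target=syn.prevalence_target,
    )
    occ = generate_occurrences(
        baseline, niche, seed=derive_seed(seed, "occ"), species=syn.species
    )
    rng = derive_rng(seed, "population_cells")
    pop_cells = rng.choice(
        baseline.data["cell_id"].to_numpy(), size=syn.n_populations, replace=False
    )
    resp = GrowthResponseSpec(**syn.growth_response)
    growth_obs, growth_truth = generate_growth_data(
        baseline,
        list(pop_cells),
        syn.n_fish_per_pop,
        syn.max_age,
        resp,
        seed=derive_seed(seed, "growth"),
    )
    if outdir:
        write_climate_csv(baseline, outdir / "climate_baseline.csv")
        occ.records.assign(species=occ.species).to_csv(
            outdir / "occurrences.csv", index=False
        )
        growth_obs.to_csv(outdir / "growth_observations.csv", index=False)
    timings["synthetic_data"] = time.perf_counter() - t0

    # -- climate preparation --------------------------------------------
    t0 = stage("climate_prep")
    candidates = cfg.candidate_variables or [
        v for v in CORE_VARIABLES if v in baseline.variables
    ]
    retained = reduce_variables(
        baseline, candidate_order=candidates, threshold=cfg.correlation_threshold
    )
    if outdir:
        (outdir / "variables.json").write_text(
            json.dumps({"candidates": candidates, "retained": retained}, indent=2)
        )
    timings["climate_prep"] = time.perf_counter() - t0

    # -- growth core -----------------------------------------------------
    t0 = stage("growth_core")
    growth_params = fit_populations(growth_obs)
    growth_params = growth_params.loc[
        growth_params["converged"] & (growth_params["K_per_yr"] > 0)
    ].reset_index(drop=True)
    if outdir:
        growth_params.to_csv(outdir / "growth_params.csv", index=False)
    timings["growth_core"] = time.perf_counter() - t0

    # -- distribution-climate ensemble ----------------------------------
    t0 = stage("sdm_ensemble")
    sdm_model = fit_sdm_ensemble(
        occ,
        baseline,
        algo_ids=cfg.algorithms,
        variables=retained,
        n_reps=cfg.n_reps,
        train_frac=cfg.train_frac,
        auc_cutoff=cfg.auc_cutoff,
        seed=derive_seed(seed, "sdm"),
    )
    presence = {"baseline": predict_presence(sdm_model, baseline, cfg.presence_threshold)}
    for name, sgrid in scenario_grids.items():
        presence[name] = predict_presence(sdm_model, sgrid, cfg.presence_threshold)
    if outdir:
        manifest = {
            "species": occ.species,
            "members": [
                {"algo_id": a, "weight": w} for a, w in sdm_model.members
            ],
            "auc_cutoff": cfg.auc_cutoff,
            "presence_threshold": cfg.presence_threshold,
            "mean_auc": {
                a: r.mean_auc for a, r in sdm_model.reports.items()
            },
            "ensemble_auc_resubstitution": sdm_model.ensemble_auc_resub,
            "ensemble_auc_holdout": sdm_model.ensemble_auc_holdout,
        }
        (outdir / "sdm_manifest.json").write_text(json.dumps(manifest, indent=2))
        for name, pg in presence.items():
            pg.to_frame().to_csv(outdir / f"presence_{name}.csv", index=False)
    timings["sdm_ensemble"] = time.perf_counter() - t0

    # -- growth-climate models -------------------------------------------
    t0 = stage("growth_climate_models")
    table = growth_params.merge(
        baseline.data[["cell_id", *retained]], on="cell_id", how="left"
    )
    ens_linf = fit_growth_ensemble(table, "Linf_mm", retained, cfg.growth_families)
    ens_k = fit_growth_ensemble(table, "K_per_yr", retained, cfg.growth_families)
    populations = growth_params[["population_id", "cell_id"]]
    projections = {
        "baseline": project_growth(ens_linf, ens_k, baseline, populations)
    }
    for name, sgrid in scenario_grids.items():
        projections[name] = project_growth(ens_linf, ens_k, sgrid, populations)
    if outdir:
        gmanifest = {
            tgt: {
                "members": [
                    {"family": f, "weight": w, "gcv": ens.models[f].gcv}
                    for f, w in ens.members
                ],
                "rmse_baseline": ens.rmse_baseline,
            }
            for tgt, ens in (("Linf_mm", ens_linf), ("K_per_yr", ens_k))
        }
        (outdir / "growth_ensemble_manifest.json").write_text(
            json.dumps(gmanifest, indent=2)
        )
        pd.concat(
            [
                proj.per_population.assign(scenario=name)
                for name, proj in projections.items()
            ]
        ).to_csv(outdir / "growth_projections.csv", index=False)
    timings["growth_climate_models"] = time.perf_counter() - t0

    # -- range statistics -------------------------------------------------
    t0 = stage("range_stats")
    rows = [
        scenario_range_summary(
            presence["baseline"], presence[name], baseline, scenario_grids[name]
        )
        for name in scenario_grids
    ]
    range_table = pd.DataFrame(rows)
    if outdir:
        range_table.to_csv(outdir / "range_summary.csv", index=False)
    timings["range_stats"] = time.perf_counter() - t0

    # -- integration -------------------------------------------------------
    t0 = stage("integration")
    means_rows = []
    for s in cfg.scenarios:
        proj = projections[s.name]
        pct = float(
            range_table.loc[range_table["scenario"] == s.name, "pct_change"].iloc[0]
        )
        means_rows.append(
            {
                "scenario": s.name,
                "delta_temp": s.delta_temp,
                "pct_change": pct,
                "mean_Linf_mm": proj.mean_Linf,
                "se_Linf_mm": proj.se_Linf,
                "ci_lo_Linf_mm": proj.ci_Linf[0],
                "ci_hi_Linf_mm": proj.ci_Linf[1],
                "mean_K_per_yr": proj.mean_K,
                "se_K_per_yr": proj.se_K,
                "ci_lo_K_per_yr": proj.ci_K[0],
                "ci_hi_K_per_yr": proj.ci_K[1],
            }
        )
    growth_means = pd.DataFrame(means_rows)
    coupling = {
        "Linf_mm": fit_coupling_regression(
            growth_means["pct_change"], growth_means["mean_Linf_mm"], target="Linf_mm"
        ),
        "K_per_yr": fit_coupling_regression(
            growth_means["pct_change"], growth_means["mean_K_per_yr"], target="K_per_yr"
        ),
    }
    ordered = sorted(cfg.scenarios, key=lambda s: s.delta_temp)
    curve_scenarios = ["baseline", ordered[0].name, ordered[-1].name]
    curves = [
        build_growth_curves(projections[name], syn.max_age)
        for name in dict.fromkeys(curve_scenarios)
    ]
    report = scenario_report(
        [
            {
                "species": occ.species,
                "range_table": range_table,
                "growth_means": growth_means,
                "coupling": list(coupling.values()),
                "curves": curves,
            }
        ],
        seed=seed,
        config={"hash": _config_hash(cfg)},
    )
    if outdir:
        growth_means.to_csv(outdir / "growth_means.csv", index=False)
        pd.DataFrame([dataclasses.asdict(c) for c in coupling.values()]).to_csv(
            outdir / "coupling_regressions.csv", index=False
        )
        pd.concat(
            [cs.curve.assign(scenario=cs.scenario_name) for cs in curves]
        ).to_csv(outdir / "growth_curves.csv", index=False)
        (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    timings["integration"] = time.perf_counter() - t0
    if outdir:
        (outdir / "run_manifest.json").write_text(
            json.dumps(
                {
                    "seed": seed,
                    "config_hash": _config_hash(cfg),
                    "stage_seconds": {k: round(v, 3) for k, v in timings.items()},
                },
                indent=2,
            )
        )
    log.info("pipeline complete: %s", {k: round(v, 1) for k, v in timings.items()})

    return RunResult(
        config=cfg,
        baseline_grid=baseline,
        scenario_grids=scenario_grids,
        retained_variables=retained,
        occurrences=occ,
        growth_params=growth_params,
        sdm=sdm_model,
        presence=presence,
        growth_ensembles={"Linf_mm": ens_linf, "K_per_yr": ens_k},
        projections=projections,
        range_table=range_table,
        growth_means=growth_means,
        coupling=coupling,
        curves=curves,
        report=report,
        timings=timings,
    )
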