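"""End-to-end orchestration: build inputs, calibrate incidence, run scenarios.

``prepare`` turns a declarative :class:`~scitsim.config.RunConfig` into
concrete model inputs: it generates or loads the population projection and
transition matrices, initialises the base-year prevalent pool, and
calibrates the yearly incident cohorts against the no-SCIT baseline so that
the diseased total tracks the population under risk.  ``run_scenarios`` then
propagates any set of scenario specs through the Markov engine.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace
from typing import Iterable

import pandas as pd

from .config import RunConfig, matrices_from_yaml
from .economics import ModelInputs, RunResult, compare_to_status_quo, run_scenario
from .population import (
    IncidenceSchedule,
    PopulationProjection,
    calibrate_incidence,
    entrant_template,
    initial_prevalent_pool,
)
from .scenarios import ScenarioSpec, builtin_scenarios, no_scit_scenario
from .synthetic import default_transition_params, generate_population_projection

__all__ = ["PreparedModel", "prepare", "run_scenarios", "run_analysis"]


@dataclass
class PreparedModel:
    """A run-ready model: config plus fully materialised inputs."""

    config: RunConfig
    projection: PopulationProjection
    inputs: ModelInputs


def build_projection(config: RunConfig) -> PopulationProjection:
    src = config.population
    if src.kind == "csv":
        return PopulationProjection.read_csv(src.path)
    return generate_population_projection(
        base_pop_6_65=src.base_pop_6_65,
        annual_trend=src.annual_trend,
        age_profile=src.age_profile,
        seed=src.seed,
    )


def build_matrices(config: RunConfig):
    src = config.transitions
    if src.kind == "file":
        return matrices_from_yaml(src.path)
    return default_transition_params(
        effect_size=src.effect_size, seed=src.seed, jitter=src.jitter
    )


def prepare(config: RunConfig) -> PreparedModel:
    """Materialise all inputs for a config, including calibrated incidence."""
    projection = build_projection(config)
    matrices = build_matrices(config)
    start, end = config.horizon
    pool = initial_prevalent_pool(projection, config.prevalence, start, config.split)
    template = entrant_template(config.prevalence, config.split)

    base_inputs = ModelInputs(
        initial_pool=pool,
        matrices=matrices,
        incidence=IncidenceSchedule({}),
        costs=config.costs,
        scit_costs=config.scit_costs,
        discount=config.discount,
        horizon=config.horizon,
        allocation=config.allocation,
    )

    def run_baseline(schedule: IncidenceSchedule) -> pd.Series:
        trial = dc_replace(base_inputs, incidence=schedule)
        return run_scenario(no_scit_scenario(), trial).by_year["diseased"]

    incidence = calibrate_incidence(
        projection,
        run_baseline,
        template,
        base_year=start,
        horizon_end=end,
        rel_tol=config.calibration.rel_tol,
        max_iter=config.calibration.max_iter,
    )
    inputs = dc_replace(base_inputs, incidence=incidence)
    return PreparedModel(config=config, projection=projection, inputs=inputs)


def run_scenarios(
    prepared: PreparedModel, specs: Iterable[ScenarioSpec] | None = None
) -> dict[str, RunResult]:
    """Run a set of scenarios (default: the five built-ins) on prepared inputs."""
    if specs is None:
        specs = builtin_scenarios()
    return {spec.name: run_scenario(spec, prepared.inputs) for spec in specs}


def run_analysis(
    config: RunConfig, specs: Iterable[ScenarioSpec] | None = None
) -> tuple[dict[str, RunResult], pd.DataFrame]:
    """Prepare, run and summarise: returns per-scenario results and the
    status-quo comparison table (empty if status_quo was not among the runs)."""
    prepared = prepare(config)
    results = run_scenarios(prepared, specs)
    if "status_quo" in results and len(results) > 1:
        summary = compare_to_status_quo(results)
    else:
        summary = pd.DataFrame(
            columns=["delta_mean_annual_cost", "delta_mean_annual_healed",
                     "cost_per_additional_healed"]
        )
    return results, summary
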