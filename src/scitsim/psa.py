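"""Probabilistic sensitivity analysis (PSA).

All scenarios are recalculated under randomly varied input parameters to
quantify output dispersion (reported as mean +/- SD over replicates, 1,000
by default).  Each parameter is drawn independently and uniformly from its
declared [low, high] range - the base-case ranges bracket the point values
used in the deterministic analysis - and is held constant over the whole
40-year run.  Draws are shared across scenarios within a replicate (common
random numbers), so scenario differences are never sampling noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .config import RunConfig, TransitionSource
from .economics import DiscountSpec, ScitCostSchedule, CostTable
from .pipeline import prepare, run_scenarios
from .population import PrevalenceTable
from .scenarios import ScenarioSpec, builtin_scenarios
from .states import AgeGroup, DiseaseState

__all__ = ["ParameterRanges", "ParameterDraw", "PsaSummary",
           "sample_parameters", "apply_draw", "run_psa"]

Range = tuple[float, float]

_DEFAULT_PREV_AR: dict[AgeGroup, Range] = {
    AgeGroup.CHILDREN: (0.03, 0.07),
    AgeGroup.ADOLESCENTS: (0.10, 0.20),
    AgeGroup.ADULTS: (0.15, 0.20),
}
_DEFAULT_PREV_AA: dict[AgeGroup, Range] = {
    AgeGroup.CHILDREN: (0.02, 0.05),
    AgeGroup.ADOLESCENTS: (0.04, 0.07),
    AgeGroup.ADULTS: (0.02, 0.05),
}
_DEFAULT_STATE_COST: dict[tuple[AgeGroup, DiseaseState], Range] = {
    (AgeGroup.CHILDREN, DiseaseState.A): (19.0, 35.0),
    (AgeGroup.CHILDREN, DiseaseState.B): (83.0, 155.0),
    (AgeGroup.CHILDREN, DiseaseState.C): (197.0, 367.0),
    (AgeGroup.CHILDREN, DiseaseState.D): (312.0, 580.0),
    (AgeGroup.ADOLESCENTS, DiseaseState.A): (13.0, 23.0),
    (AgeGroup.ADOLESCENTS, DiseaseState.B): (68.0, 126.0),
    (AgeGroup.ADOLESCENTS, DiseaseState.C): (181.0, 337.0),
    (AgeGroup.ADOLESCENTS, DiseaseState.D): (309.0, 575.0),
    (AgeGroup.ADULTS, DiseaseState.A): (6.0, 10.0),
    (AgeGroup.ADULTS, DiseaseState.B): (55.0, 103.0),
    (AgeGroup.ADULTS, DiseaseState.C): (159.0, 295.0),
    (AgeGroup.ADULTS, DiseaseState.D): (309.0, 575.0),
}
_DEFAULT_SCIT_COST: dict[int, Range] = {
    1: (262.0, 502.0),
    2: (262.0, 480.0),
    3: (262.0, 480.0),
}


@dataclass(frozen=True)
class ParameterRanges:
    """[low, high] sampling bounds per varied parameter.

    Defaults bracket the base-case point values: prevalences, the seasonal
    share (45-75%), state costs, yearly SCIT drug costs and the discount
    rate (1.5-2.5%/a).  ``transition_jitter`` is the scale of multiplicative
    perturbation applied to the synthetic transition matrices; its default
    range (0, 0) leaves the matrices unvaried.
    """

    prevalence_ar: Mapping[AgeGroup, Range] = field(
        default_factory=lambda: dict(_DEFAULT_PREV_AR))
    prevalence_aa: Mapping[AgeGroup, Range] = field(
        default_factory=lambda: dict(_DEFAULT_PREV_AA))
    seasonal_share: Range = (0.45, 0.75)
    state_cost: Mapping[tuple[AgeGroup, DiseaseState], Range] = field(
        default_factory=lambda: dict(_DEFAULT_STATE_COST))
    scit_cost: Mapping[int, Range] = field(
        default_factory=lambda: dict(_DEFAULT_SCIT_COST))
    discount_rate: Range = (0.015, 0.025)
    transition_jitter: Range = (0.0, 0.0)

    def __post_init__(self) -> None:
        def check(name: str, rng: Range) -> None:
            lo, hi = rng
            if lo > hi:
                raise ValueError(f"range for {name} has low > high: ({lo}, {hi})")

        for g, r in self.prevalence_ar.items():
            check(f"prevalence_ar[{g.value}]", r)
        for g, r in self.prevalence_aa.items():
            check(f"prevalence_aa[{g.value}]", r)
        check("seasonal_share", self.seasonal_share)
        for k, r in self.state_cost.items():
            check(f"state_cost[{k}]", r)
        for y, r in self.scit_cost.items():
            check(f"scit_cost[year {y}]", r)
        check("discount_rate", self.discount_rate)
        check("transition_jitter", self.transition_jitter)


@dataclass(frozen=True)
class ParameterDraw:
    """One replicate's concrete parameter values."""

    prevalence_ar: dict[AgeGroup, float]
    prevalence_aa: dict[AgeGroup, float]
    seasonal_share: float
    state_cost: dict[tuple[AgeGroup, DiseaseState], float]
    scit_cost: dict[int, float]
    discount_rate: float
    transition_jitter: float
    transition_seed: int


def _u(rng: np.random.Generator, r: Range) -> float:
    lo, hi = r
    return lo if lo == hi else float(rng.uniform(lo, hi))


def sample_parameters(
    ranges: ParameterRanges, rng: np.random.Generator | int
) -> ParameterDraw:
    """Draw one parameter set, uniformly and independently within each range."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return ParameterDraw(
        prevalence_ar={g: _u(rng, r) for g, r in ranges.prevalence_ar.items()},
        prevalence_aa={g: _u(rng, r) for g, r in ranges.prevalence_aa.items()},
        seasonal_share=_u(rng, ranges.seasonal_share),
        state_cost={k: _u(rng, r) for k, r in ranges.state_cost.items()},
        scit_cost={y: _u(rng, r) for y, r in ranges.scit_cost.items()},
        discount_rate=_u(rng, ranges.discount_rate),
        transition_jitter=_u(rng, ranges.transition_jitter),
        transition_seed=int(rng.integers(0, 2**31 - 1)),
    )


def apply_draw(config: RunConfig, draw: ParameterDraw) -> RunConfig:
    """Rebuild a run configuration with one replicate's drawn parameters.

    The drawn yearly SCIT cost replaces the preseasonal/perennial mean (both
    application forms are set to the drawn value); a positive transition
    jitter re-generates the synthetic matrices with seeded noise.
    """
    scit = tuple(draw.scit_cost[y] for y in (1, 2, 3))
    transitions = config.transitions
    if transitions.kind == "synthetic" and draw.transition_jitter > 0:
        transitions = dc_replace(
            transitions, jitter=draw.transition_jitter, seed=draw.transition_seed
        )
    return dc_replace(
        config,
        prevalence=PrevalenceTable(
            ar=dict(draw.prevalence_ar),
            aa=dict(draw.prevalence_aa),
            seasonal_share=draw.seasonal_share,
        ),
        costs=CostTable(dict(draw.state_cost)),
        scit_costs=ScitCostSchedule(preseasonal=scit, perennial=scit,
                                    mean_mode=True),
        discount=DiscountSpec(annual_rate=draw.discount_rate,
                              base_year=config.discount.base_year),
        transitions=transitions,
    )


#: RunResult columns summarised per scenario.
PSA_OUTPUTS = ("diseased", "total_cost_discounted", "scit_cost")


@dataclass
class PsaSummary:
    """Mean and SD of mean-annual outputs over replicates, per scenario."""

    table: pd.DataFrame  # index (scenario, output); columns mean, sd
    n_reps: int
    seed: int
    replicates: pd.DataFrame  # one row per (replicate, scenario)

    def mean(self, scenario: str, output: str) -> float:
        return float(self.table.loc[(scenario, output), "mean"])

    def sd(self, scenario: str, output: str) -> float:
        return float(self.table.loc[(scenario, output), "sd"])


def run_psa(
    config: RunConfig,
    scenarios: Iterable[ScenarioSpec] | None = None,
    ranges: ParameterRanges | None = None,
    n_reps: int = 1000,
    seed: int = 0,
) -> PsaSummary:
    """Re-run all scenarios ``n_reps`` times under randomly drawn parameters.

    Each replicate draws one parameter set from ``ranges`` and re-prepares
    the model (including incidence re-calibration) before running every
    scenario on the same draw.  Replicate seeds are spawned from ``seed``, so
    the first k replicates of a longer run match a shorter run exactly.
    Reported outputs are mean-annual diseased persons, discounted total cost
    and SCIT drug cost.
    """
    if n_reps < 2:
        raise ValueError(f"n_reps must be >= 2, got {n_reps}")
    if scenarios is None:
        scenarios = builtin_scenarios()
    scenarios = list(scenarios)
    if ranges is None:
        ranges = ParameterRanges()

    children = np.random.SeedSequence(seed).spawn(n_reps)
    rows = []
    for rep, child in enumerate(children):
        try:
            draw = sample_parameters(ranges, np.random.default_rng(child))
            rep_config = apply_draw(config, draw)
            prepared = prepare(rep_config)
            results = run_scenarios(prepared, scenarios)
        except Exception as exc:
            raise RuntimeError(
                f"PSA replicate {rep} (seed {seed}) failed: {exc}"
            ) from exc
        for name, res in results.items():
            rows.append(
                {
                    "replicate": rep,
                    "scenario": name,
                    "diseased": res.mean_annual("diseased"),
                    "total_cost_discounted": res.mean_annual("total_cost_discounted"),
                    "scit_cost": res.mean_annual("scit_cost"),
                }
            )
    replicates = pd.DataFrame(rows)
    long = replicates.melt(
        id_vars=["replicate", "scenario"],
        value_vars=list(PSA_OUTPUTS),
        var_name="output",
    )
    table = (
        long.groupby(["scenario", "output"])["value"]
        .agg(mean="mean", sd=lambda s: s.std(ddof=1))
        .sort_index()
    )
    return PsaSummary(table=table, n_reps=n_reps, seed=seed, replicates=replicates)
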