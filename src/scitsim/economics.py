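"""Payer-perspective cost accounting, discounting, the scenario engine, ICERs.

Costs have two components: yearly state costs (per age group and disease
state A-D; the healthy and death states cost nothing) and SCIT drug costs for
the three therapy years of a course.  All costs are discounted to the base
year at a fixed annual rate (2% by default).  Indirect/societal costs and
outpatient visit costs are outside the payer perspective and not modelled.

``run_scenario`` propagates the stratified cohort through the yearly loop -
incident entrants, SCIT allocation, census and cost accrual, Markov
transitions, therapy-year promotion, cohort ageing - and returns a
``RunResult`` with per-year occupancies and cost components.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from .markov import advance_stratified, validate_matrix
from .population import IncidenceSchedule
from .scenarios import ScenarioSpec, allocate_scit
from .states import (
    N_STATES,
    AgeGroup,
    AllergyType,
    Arm,
    DiseaseState,
    StratumKey,
)

__all__ = [
    "CostTable",
    "ScitCostSchedule",
    "DiscountSpec",
    "ModelInputs",
    "RunResult",
    "annual_state_cost",
    "scit_mean_cost",
    "discount",
    "run_scenario",
    "icer",
    "compare_to_status_quo",
    "DOMINANT",
]

#: Marker returned by :func:`icer` when a scenario saves money and heals more.
DOMINANT = "dominant"

_COSTED_STATES = (DiseaseState.A, DiseaseState.B, DiseaseState.C, DiseaseState.D)

_DEFAULT_STATE_COSTS: dict[tuple[AgeGroup, DiseaseState], float] = {
    # Euro per person-year, third-party-payer perspective
    (AgeGroup.CHILDREN, DiseaseState.A): 27.0,
    (AgeGroup.CHILDREN, DiseaseState.B): 119.0,
    (AgeGroup.CHILDREN, DiseaseState.C): 282.0,
    (AgeGroup.CHILDREN, DiseaseState.D): 446.0,
    (AgeGroup.ADOLESCENTS, DiseaseState.A): 18.0,
    (AgeGroup.ADOLESCENTS, DiseaseState.B): 97.0,
    (AgeGroup.ADOLESCENTS, DiseaseState.C): 259.0,
    (AgeGroup.ADOLESCENTS, DiseaseState.D): 442.0,
    (AgeGroup.ADULTS, DiseaseState.A): 8.0,
    (AgeGroup.ADULTS, DiseaseState.B): 79.0,
    (AgeGroup.ADULTS, DiseaseState.C): 227.0,
    (AgeGroup.ADULTS, DiseaseState.D): 442.0,
}


@dataclass(frozen=True)
class CostTable:
    """Annual state costs in Euro per (age group, disease state A-D)."""

    state_cost: Mapping[tuple[AgeGroup, DiseaseState], float] = field(
        default_factory=lambda: dict(_DEFAULT_STATE_COSTS)
    )

    def __post_init__(self) -> None:
        for group in AgeGroup:
            for state in _COSTED_STATES:
                if (group, state) not in self.state_cost:
                    raise ValueError(
                        f"missing state cost for ({group.value}, {state.name})"
                    )
                c = self.state_cost[(group, state)]
                if not (math.isfinite(c) and c >= 0):
                    raise ValueError(
                        f"state cost for ({group.value}, {state.name}) invalid: {c}"
                    )

    def vector(self, group: AgeGroup) -> np.ndarray:
        """Length-6 cost vector for one age group (E and F are zero)."""
        v = np.zeros(N_STATES)
        for state in _COSTED_STATES:
            v[int(state)] = self.state_cost[(group, state)]
        return v


@dataclass(frozen=True)
class ScitCostSchedule:
    """SCIT drug costs in Euro per therapy year (1-3).

    Preseasonal application costs 262 Euro in each of the three years;
    perennial application 502 / 480 / 480 Euro.  In ``mean_mode`` (the
    default) every treated patient is charged the arithmetic mean of the two
    application forms - 382 Euro in year 1 and 371 Euro in years 2-3 -
    regardless of allergy type; otherwise seasonal patients are charged the
    preseasonal and perennial patients the perennial schedule.
    """

    preseasonal: tuple[float, float, float] = (262.0, 262.0, 262.0)
    perennial: tuple[float, float, float] = (502.0, 480.0, 480.0)
    mean_mode: bool = True

    def __post_init__(self) -> None:
        for name in ("preseasonal", "perennial"):
            arm = getattr(self, name)
            if len(arm) != 3 or any(c < 0 or not math.isfinite(c) for c in arm):
                raise ValueError(f"{name} costs must be three non-negative values: {arm}")

    def _check_year(self, therapy_year: int) -> int:
        if therapy_year not in (1, 2, 3):
            raise ValueError(f"therapy_year must be 1, 2 or 3, got {therapy_year}")
        return therapy_year - 1

    def mean_cost(self, therapy_year: int) -> float:
        i = self._check_year(therapy_year)
        return (self.preseasonal[i] + self.perennial[i]) / 2.0

    def cost(self, therapy_year: int, atype: AllergyType | None = None) -> float:
        i = self._check_year(therapy_year)
        if self.mean_mode or atype is None:
            return self.mean_cost(therapy_year)
        arm = self.preseasonal if atype is AllergyType.SEASONAL else self.perennial
        return arm[i]


def scit_mean_cost(s: ScitCostSchedule, therapy_year: int) -> float:
    """Arithmetic mean of preseasonal and perennial cost for one therapy year."""
    return s.mean_cost(therapy_year)


@dataclass(frozen=True)
class DiscountSpec:
    """Annual discounting of future costs to the base year (default 2%/a)."""

    annual_rate: float = 0.02
    base_year: int = 2011

    def __post_init__(self) -> None:
        if not (0.0 <= self.annual_rate <= 0.10):
            raise ValueError(f"discount rate out of [0, 0.10]: {self.annual_rate}")

    def factor(self, year: int) -> float:
        if year < self.base_year:
            raise ValueError(f"year {year} precedes base year {self.base_year}")
        return 1.0 / (1.0 + self.annual_rate) ** (year - self.base_year)


def discount(amount: float, year: int, spec: DiscountSpec) -> float:
    """Present value at the base year: amount / (1 + rate)^(year - base_year)."""
    return amount * spec.factor(year)


def annual_state_cost(
    cohorts: Mapping[StratumKey, np.ndarray], table: CostTable
) -> float:
    """State costs for one year: sum over strata of counts x age-group costs."""
    total = 0.0
    for key, vec in cohorts.items():
        total += float(np.asarray(vec, dtype=float) @ table.vector(key.age_group))
    return total


@dataclass
class ModelInputs:
    """Everything a scenario run needs besides the scenario itself."""

    initial_pool: dict[StratumKey, np.ndarray]
    matrices: Mapping[tuple[AgeGroup, AllergyType, Arm], np.ndarray]
    incidence: IncidenceSchedule
    costs: CostTable = field(default_factory=CostTable)
    scit_costs: ScitCostSchedule = field(default_factory=ScitCostSchedule)
    discount: DiscountSpec = field(default_factory=DiscountSpec)
    horizon: tuple[int, int] = (2011, 2050)
    allocation: Literal["flow", "stock"] = "flow"

    def __post_init__(self) -> None:
        for k, m in self.matrices.items():
            try:
                validate_matrix(m)
            except ValueError as exc:
                raise ValueError(f"invalid matrix for {k}: {exc}") from exc
        start, end = self.horizon
        if not (2011 <= start < end <= 2050):
            raise ValueError(f"horizon must satisfy 2011 <= start < end <= 2050: "
                             f"{self.horizon}")

    def matrix_for(self, key: StratumKey) -> np.ndarray:
        try:
            return self.matrices[key.matrix_key]
        except KeyError:
            raise KeyError(f"no transition matrix for stratum {key}") from None


@dataclass
class RunResult:
    """Per-year occupancies and costs for one scenario run.

    ``by_year`` is indexed by calendar year with columns: the six state
    totals ``A``..``F``, ``diseased`` (A-D), ``healed`` (E), ``on_scit``,
    ``state_cost``, ``scit_cost``, ``total_cost`` and
    ``total_cost_discounted`` (Euro).  Occupancies are the during-year census
    taken after this year's SCIT allocation and before transitions.
    """

    scenario: str
    by_year: pd.DataFrame
    final_cohorts: dict[StratumKey, np.ndarray]

    def mean_annual(self, column: str) -> float:
        return float(self.by_year[column].mean())

    @property
    def mean_annual_diseased(self) -> float:
        return self.mean_annual("diseased")

    @property
    def mean_annual_healed(self) -> float:
        return self.mean_annual("healed")

    def mean_annual_cost(self, discounted: bool = True) -> float:
        return self.mean_annual("total_cost_discounted" if discounted else "total_cost")


def _promote_therapy_years(
    cohorts: dict[StratumKey, np.ndarray]
) -> dict[StratumKey, np.ndarray]:
    """Advance SCIT therapy-year counters; completed courses move to POST."""
    out: dict[StratumKey, np.ndarray] = {}
    for key, vec in cohorts.items():
        if key.arm is Arm.SCIT:
            if key.therapy_year < 3:
                nkey = StratumKey(key.age_group, key.allergy_type, Arm.SCIT,
                                  key.therapy_year + 1)
            else:
                nkey = StratumKey(key.age_group, key.allergy_type, Arm.POST)
        else:
            nkey = key
        out[nkey] = out.get(nkey, np.zeros(N_STATES)) + vec
    return out


def run_scenario(spec: ScenarioSpec, inputs: ModelInputs) -> RunResult:
    """Run one scenario over the model horizon.

    Yearly loop: add this year's incident entrants (base year starts from the
    prevalent pool instead), allocate eligible ST patients to SCIT, take the
    during-year census and accrue state and SCIT drug costs, then apply the
    Markov transitions, promote SCIT therapy years (year 3 completers move to
    the post-SCIT arm), and age the cohorts into the next calendar year.
    """
    from .population import age_cohorts  # local import avoids cycle at module load

    start, end = inputs.horizon
    cohorts = {k: np.asarray(v, dtype=float).copy()
               for k, v in inputs.initial_pool.items()}
    rows = []
    for year in range(start, end + 1):
        try:
            if year > start:
                for key, vec in inputs.incidence.for_year(year).items():
                    cohorts[key] = cohorts.get(key, np.zeros(N_STATES)) + vec
            cohorts = allocate_scit(cohorts, spec, year, mode=inputs.allocation)

            state_totals = np.zeros(N_STATES)
            scit_cost = 0.0
            on_scit = 0.0
            for key, vec in cohorts.items():
                state_totals += vec
                if key.arm is Arm.SCIT:
                    n = float(vec[:int(DiseaseState.F)].sum())  # the dead pay nothing
                    on_scit += n
                    scit_cost += n * inputs.scit_costs.cost(
                        key.therapy_year, key.allergy_type
                    )
            state_cost = annual_state_cost(cohorts, inputs.costs)
            total = state_cost + scit_cost
            rows.append(
                {
                    "year": year,
                    **{s.name: state_totals[int(s)] for s in DiseaseState},
                    "diseased": float(state_totals[:4].sum()),
                    "healed": float(state_totals[int(DiseaseState.E)]),
                    "on_scit": on_scit,
                    "state_cost": state_cost,
                    "scit_cost": scit_cost,
                    "total_cost": total,
                    "total_cost_discounted": discount(total, year, inputs.discount),
                }
            )

            matrices = {k: inputs.matrix_for(k) for k in cohorts}
            cohorts = advance_stratified(cohorts, matrices)
            cohorts = _promote_therapy_years(cohorts)
            cohorts = age_cohorts(cohorts)
        except Exception as exc:
            raise RuntimeError(
                f"scenario {spec.name!r} failed in model year {year}: {exc}"
            ) from exc
    by_year = pd.DataFrame(rows).set_index("year")
    return RunResult(spec.name, by_year, cohorts)


def icer(delta_cost: float, delta_healed: float) -> int | str:
    """Cost per additionally healed patient versus the comparator.

    ``delta_cost`` and ``delta_healed`` are mean annual differences.  A
    positive cost difference yields the ratio rounded to the nearest Euro; a
    negative cost difference with a positive health gain means the scenario
    dominates the comparator.  A non-positive health gain has no defined
    ratio and raises ``ValueError``.
    """
    if delta_healed <= 0:
        raise ValueError(
            f"ICER undefined for non-positive effect difference ({delta_healed:g})"
        )
    if delta_cost < 0:
        return DOMINANT
    return int(round(delta_cost / delta_healed))


def compare_to_status_quo(
    results: Mapping[str, RunResult],
    baseline: str = "status_quo",
    discounted: bool = True,
) -> pd.DataFrame:
    """Tabulate each scenario against the status quo.

    Columns: mean annual cost difference (Euro), mean annual additional
    healed patients, and the cost per additionally healed patient (integer
    Euro, ``"dominant"`` for cost-saving scenarios, ``"n/a"`` when the
    effect difference is not positive).
    """
    if baseline not in results:
        raise KeyError(f"baseline scenario {baseline!r} missing from results")
    ref = results[baseline]
    rows = []
    for name, res in results.items():
        if name == baseline:
            continue
        d_cost = res.mean_annual_cost(discounted) - ref.mean_annual_cost(discounted)
        d_healed = res.mean_annual_healed - ref.mean_annual_healed
        if d_healed > 0:
            ratio: int | str = icer(d_cost, d_healed)
        else:
            ratio = "n/a"
        rows.append(
            {
                "scenario": name,
                "delta_mean_annual_cost": d_cost,
                "delta_mean_annual_healed": d_healed,
                "cost_per_additional_healed": ratio,
            }
        )
    return pd.DataFrame(rows).set_index("scenario")
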