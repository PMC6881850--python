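"""Policy scenarios: SCIT supply-rate schedules and eligible-state sets.

A supply schedule gives, per (age group, allergy type), the proportion of
eligible symptomatic-therapy patients who start a subcutaneous immunotherapy
(SCIT) course in a year.  Rates change linearly from their 2011 level to a
target level in a target year and stay constant thereafter.  A scenario is a
schedule plus the set of disease states in which therapy may start.

The five built-in scenarios:

* ``status_quo`` - 2011 uptake (seasonal 5/15/20%, perennial 5/10/20% for
  children/adolescents/adults) rising to 10/20/30% resp. 5/15/30% by 2030;
  therapy onset in states C and D only.
* ``scenario_1`` - 2011 rates tripled by 2020; onset in C and D.
* ``scenario_2`` - 75% for all groups by 2020; onset in C and D.
* ``scenario_3`` - status-quo schedule; onset extended to states B, C, D.
* ``scenario_4`` - status-quo schedule; onset in all states A-D.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Mapping

import numpy as np

from .states import (
    AgeGroup,
    AllergyType,
    Arm,
    DiseaseState,
    StratumKey,
    scit_stratum,
)

__all__ = [
    "SupplySchedule",
    "ScenarioSpec",
    "builtin_scenarios",
    "no_scit_scenario",
    "supply_rate",
    "allocate_scit",
    "BASELINE_RATES_2011",
]

RateTable = Mapping[tuple[AgeGroup, AllergyType], float]

#: 2011 SCIT supply rates per (age group, allergy type).
BASELINE_RATES_2011: dict[tuple[AgeGroup, AllergyType], float] = {
    (AgeGroup.CHILDREN, AllergyType.SEASONAL): 0.05,
    (AgeGroup.ADOLESCENTS, AllergyType.SEASONAL): 0.15,
    (AgeGroup.ADULTS, AllergyType.SEASONAL): 0.20,
    (AgeGroup.CHILDREN, AllergyType.PERENNIAL): 0.05,
    (AgeGroup.ADOLESCENTS, AllergyType.PERENNIAL): 0.10,
    (AgeGroup.ADULTS, AllergyType.PERENNIAL): 0.20,
}

_STATUS_QUO_TARGETS_2030: dict[tuple[AgeGroup, AllergyType], float] = {
    (AgeGroup.CHILDREN, AllergyType.SEASONAL): 0.10,
    (AgeGroup.ADOLESCENTS, AllergyType.SEASONAL): 0.20,
    (AgeGroup.ADULTS, AllergyType.SEASONAL): 0.30,
    (AgeGroup.CHILDREN, AllergyType.PERENNIAL): 0.05,
    (AgeGroup.ADOLESCENTS, AllergyType.PERENNIAL): 0.15,
    (AgeGroup.ADULTS, AllergyType.PERENNIAL): 0.30,
}


def _check_rates(name: str, rates: RateTable) -> None:
    for group in AgeGroup:
        for atype in AllergyType:
            if (group, atype) not in rates:
                raise ValueError(f"{name} missing rate for ({group.value}, {atype.value})")
            r = rates[(group, atype)]
            if not (0.0 <= r <= 1.0):
                raise ValueError(f"{name} rate out of [0,1] for "
                                 f"({group.value}, {atype.value}): {r}")


@dataclass(frozen=True)
class SupplySchedule:
    """Linear ramp of SCIT supply rates from 2011 to a target year."""

    rate_2011: RateTable
    rate_target: RateTable
    target_year: int
    interpolation: Literal["linear"] = "linear"

    def __post_init__(self) -> None:
        _check_rates("rate_2011", self.rate_2011)
        _check_rates("rate_target", self.rate_target)
        if not (2011 < self.target_year <= 2050):
            raise ValueError(f"target_year must be in (2011, 2050], got {self.target_year}")
        if self.interpolation != "linear":
            raise ValueError(f"unsupported interpolation {self.interpolation!r}")

    def rate(self, group: AgeGroup, atype: AllergyType, year: int) -> float:
        if not (2011 <= year <= 2050):
            raise ValueError(f"year {year} outside 2011-2050")
        r0 = self.rate_2011[(group, atype)]
        r1 = self.rate_target[(group, atype)]
        if year >= self.target_year:
            return r1
        return r0 + (r1 - r0) * (year - 2011) / (self.target_year - 2011)


def supply_rate(
    s: SupplySchedule, group: AgeGroup, atype: AllergyType, year: int
) -> float:
    """SCIT supply rate for one group/type/year (linear ramp, then constant)."""
    return s.rate(group, atype, year)


@dataclass(frozen=True)
class ScenarioSpec:
    """One policy scenario: a supply schedule and the SCIT-eligible states."""

    name: str
    schedule: SupplySchedule
    eligible_states: frozenset[DiseaseState] = field(
        default_factory=lambda: frozenset({DiseaseState.C, DiseaseState.D})
    )

    def __post_init__(self) -> None:
        if not self.eligible_states:
            raise ValueError("eligible_states must be non-empty")
        bad = self.eligible_states - {
            DiseaseState.A, DiseaseState.B, DiseaseState.C, DiseaseState.D,
        }
        if bad:
            raise ValueError(f"states not eligible for therapy onset: {sorted(bad)}")


def _status_quo_schedule() -> SupplySchedule:
    return SupplySchedule(dict(BASELINE_RATES_2011), dict(_STATUS_QUO_TARGETS_2030), 2030)


def builtin_scenarios() -> list[ScenarioSpec]:
    """The five built-in policy scenarios (status quo first)."""
    cd = frozenset({DiseaseState.C, DiseaseState.D})
    sq = _status_quo_schedule()
    tripled = {k: min(3 * v, 1.0) for k, v in BASELINE_RATES_2011.items()}
    flat75 = {k: 0.75 for k in BASELINE_RATES_2011}
    return [
        ScenarioSpec("status_quo", sq, cd),
        ScenarioSpec(
            "scenario_1", SupplySchedule(dict(BASELINE_RATES_2011), tripled, 2020), cd
        ),
        ScenarioSpec(
            "scenario_2", SupplySchedule(dict(BASELINE_RATES_2011), flat75, 2020), cd
        ),
        ScenarioSpec(
            "scenario_3", sq, frozenset({DiseaseState.B, DiseaseState.C, DiseaseState.D})
        ),
        ScenarioSpec(
            "scenario_4",
            sq,
            frozenset({DiseaseState.A, DiseaseState.B, DiseaseState.C, DiseaseState.D}),
        ),
    ]


def no_scit_scenario() -> ScenarioSpec:
    """Reference scenario with zero uptake (used for incidence calibration)."""
    zero = {k: 0.0 for k in BASELINE_RATES_2011}
    return ScenarioSpec(
        "no_scit", SupplySchedule(zero, zero, 2030),
        frozenset({DiseaseState.C, DiseaseState.D}),
    )


def allocate_scit(
    cohorts: Mapping[StratumKey, np.ndarray],
    spec: ScenarioSpec,
    year: int,
    mode: Literal["flow", "stock"] = "flow",
) -> dict[StratumKey, np.ndarray]:
    """Move this year's SCIT starters from the ST arm into therapy year 1.

    Under the default ``flow`` interpretation the supply rate is the fraction
    of the current ST-arm population in eligible states that starts a course
    this year.  Under ``stock`` the rate is read as a coverage target: the
    fraction of the eligible stock (ST + ongoing SCIT) that should be under
    therapy, and only the shortfall is newly enrolled.  Persons already in
    the SCIT or post-SCIT arms are untouched; counts are conserved exactly.
    """
    if mode not in ("flow", "stock"):
        raise ValueError(f"unknown allocation mode {mode!r}")
    out = {k: np.asarray(v, dtype=float).copy() for k, v in cohorts.items()}
    eligible_idx = [int(s) for s in spec.eligible_states]
    for group in AgeGroup:
        for atype in AllergyType:
            rate = spec.schedule.rate(group, atype, year)
            st_key = StratumKey(group, atype, Arm.ST)
            if st_key not in out:
                continue
            st_vec = out[st_key]
            if mode == "flow":
                moved = np.zeros_like(st_vec)
                moved[eligible_idx] = rate * st_vec[eligible_idx]
            else:
                in_scit = np.zeros_like(st_vec)
                for ty in (1, 2, 3):
                    k = scit_stratum(group, atype, ty)
                    if k in out:
                        in_scit += out[k]
                moved = np.zeros_like(st_vec)
                for i in eligible_idx:
                    target = rate * (st_vec[i] + in_scit[i])
                    moved[i] = min(max(target - in_scit[i], 0.0), st_vec[i])
            if moved.any():
                y1_key = scit_stratum(group, atype, 1)
                out[st_key] = st_vec - moved
                out[y1_key] = out.get(y1_key, np.zeros_like(st_vec)) + moved
    return out
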