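"""Domain types: disease states, age groups, allergy types, treatment arms, strata.

The model tracks expected person-counts through six health states:

    A  mild allergic rhinitis (AR)
    B  moderate/severe AR
    C  moderate/severe AR + mild allergic asthma (AA)
    D  severe AR + moderate/severe AA
    E  no symptoms / healthy
    F  death (absorbing)

State order is fixed as (A, B, C, D, E, F) in every array and file written by
this package.  Severity is ordered A < B < C < D; E and F sit outside the
severity order.  Sub-cohorts (strata) are the Cartesian product of age group,
allergy type and treatment arm; subcutaneous immunotherapy (SCIT) strata
additionally carry the therapy year (1-3) of the ongoing course.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterator

__all__ = [
    "DiseaseState",
    "AgeGroup",
    "AllergyType",
    "Arm",
    "StratumKey",
    "N_STATES",
    "STATE_ORDER",
    "DISEASED_STATES",
    "AGE_SPANS",
    "SCIT_YEARS",
    "all_strata",
    "st_stratum",
    "scit_stratum",
]


class DiseaseState(enum.IntEnum):
    """The six Markov states; the integer value is the array index."""

    A = 0
    B = 1
    C = 2
    D = 3
    E = 4
    F = 5


N_STATES = 6
STATE_ORDER = tuple(DiseaseState)
#: States counted as "diseased" in epidemiological aggregates.
DISEASED_STATES = (DiseaseState.A, DiseaseState.B, DiseaseState.C, DiseaseState.D)
#: States with asthma involvement (used for the AA reduction aggregate).
ASTHMA_STATES = (DiseaseState.C, DiseaseState.D)


class AgeGroup(str, enum.Enum):
    CHILDREN = "children"
    ADOLESCENTS = "adolescents"
    ADULTS = "adults"


#: Inclusive age spans in years. Disjoint, union = 6-65 (the population under risk).
AGE_SPANS: dict[AgeGroup, tuple[int, int]] = {
    AgeGroup.CHILDREN: (6, 12),
    AgeGroup.ADOLESCENTS: (13, 18),
    AgeGroup.ADULTS: (19, 65),
}


def age_span_width(group: AgeGroup) -> int:
    lo, hi = AGE_SPANS[group]
    return hi - lo + 1


class AllergyType(str, enum.Enum):
    SEASONAL = "seasonal"
    PERENNIAL = "perennial"


class Arm(str, enum.Enum):
    """Treatment arm of a sub-cohort.

    ST    symptomatic therapy (the default arm)
    SCIT  currently within a 3-year immunotherapy course
    POST  completed a SCIT course; ST dynamics/costs, not eligible for re-treatment
    """

    ST = "st"
    SCIT = "scit"
    POST = "post"


SCIT_YEARS = (1, 2, 3)


@dataclass(frozen=True, slots=True)
class StratumKey:
    """Identifies one sub-cohort: (age group, allergy type, arm[, therapy year])."""

    age_group: AgeGroup
    allergy_type: AllergyType
    arm: Arm
    therapy_year: int | None = None

    def __post_init__(self) -> None:
        if self.arm is Arm.SCIT:
            if self.therapy_year not in SCIT_YEARS:
                raise ValueError(
                    f"SCIT stratum requires therapy_year in {SCIT_YEARS}, "
                    f"got {self.therapy_year!r}"
                )
        elif self.therapy_year is not None:
            raise ValueError("therapy_year is only defined for the SCIT arm")

    @property
    def dynamics_arm(self) -> Arm:
        """Arm whose transition matrix governs this stratum (POST follows ST)."""
        return Arm.ST if self.arm is Arm.POST else self.arm

    @property
    def matrix_key(self) -> tuple[AgeGroup, AllergyType, Arm]:
        return (self.age_group, self.allergy_type, self.dynamics_arm)

    def with_age_group(self, group: AgeGroup) -> "StratumKey":
        return StratumKey(group, self.allergy_type, self.arm, self.therapy_year)

    def __str__(self) -> str:
        ty = f"/y{self.therapy_year}" if self.therapy_year else ""
        return f"{self.age_group.value}:{self.allergy_type.value}:{self.arm.value}{ty}"


def st_stratum(group: AgeGroup, atype: AllergyType) -> StratumKey:
    return StratumKey(group, atype, Arm.ST)


def scit_stratum(group: AgeGroup, atype: AllergyType, year: int) -> StratumKey:
    return StratumKey(group, atype, Arm.SCIT, year)


def all_strata() -> Iterator[StratumKey]:
    """All 30 strata: 3 age groups x 2 allergy types x (ST + SCIT y1-3 + POST)."""
    for group in AgeGroup:
        for atype in AllergyType:
            yield StratumKey(group, atype, Arm.ST)
            for year in SCIT_YEARS:
                yield StratumKey(group, atype, Arm.SCIT, year)
            yield StratumKey(group, atype, Arm.POST)
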