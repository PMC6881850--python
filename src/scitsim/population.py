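"""Population under risk, prevalent pool initialisation, ageing and incidence.

The population under risk is the German population aged 6-65, split into
children (6-12), adolescents (13-18) and adults (19-65).  A population
projection table (calendar year x single age-year) supplies its size per
year.  The 2011 prevalent pool is built from age-group prevalences of
allergic rhinitis (AR) and allergic asthma (AA); yearly incident cohorts are
calibrated so that, absent immunotherapy, the diseased total tracks the
population under risk.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .markov import validate_cohort
from .states import (
    AGE_SPANS,
    N_STATES,
    AgeGroup,
    AllergyType,
    DiseaseState,
    StratumKey,
    age_span_width,
    st_stratum,
)

__all__ = [
    "PopulationProjection",
    "PrevalenceTable",
    "SeveritySplit",
    "IncidenceSchedule",
    "population_under_risk",
    "initial_prevalent_pool",
    "age_cohorts",
    "calibrate_incidence",
    "diseased_total",
]

YEAR_MIN, YEAR_MAX = 2011, 2050
AGE_MIN, AGE_MAX = 0, 100


class PopulationProjection:
    """Person-counts per (calendar year 2011-2050, single age-year 0-100).

    Backed by a dense (40 x 101) array; constructed from a tidy DataFrame
    with columns ``year``, ``age``, ``count`` (the CSV interchange format).
    """

    def __init__(self, counts: np.ndarray):
        counts = np.asarray(counts, dtype=float)
        expected = (YEAR_MAX - YEAR_MIN + 1, AGE_MAX - AGE_MIN + 1)
        if counts.shape != expected:
            raise ValueError(f"projection array must be {expected}, got {counts.shape}")
        if not np.all(np.isfinite(counts)) or np.any(counts < 0):
            raise ValueError("projection counts must be finite and non-negative")
        self._counts = counts

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PopulationProjection":
        required = {"year", "age", "count"}
        if not required.issubset(df.columns):
            raise ValueError(f"projection table needs columns {sorted(required)}, "
                             f"got {list(df.columns)}")
        pivot = df.pivot_table(index="year", columns="age", values="count", aggfunc="sum")
        years = range(YEAR_MIN, YEAR_MAX + 1)
        ages = range(AGE_MIN, AGE_MAX + 1)
        missing_years = sorted(set(years) - set(pivot.index))
        if missing_years:
            raise ValueError(f"projection is missing years: {missing_years[:5]} ...")
        missing_ages = sorted(set(ages) - set(pivot.columns))
        if missing_ages:
            raise ValueError(f"projection is missing ages: {missing_ages[:5]} ...")
        return cls(pivot.loc[list(years), list(ages)].to_numpy())

    @classmethod
    def read_csv(cls, path) -> "PopulationProjection":
        return cls.from_frame(pd.read_csv(path))

    def to_frame(self) -> pd.DataFrame:
        years = np.repeat(np.arange(YEAR_MIN, YEAR_MAX + 1), AGE_MAX - AGE_MIN + 1)
        ages = np.tile(np.arange(AGE_MIN, AGE_MAX + 1), YEAR_MAX - YEAR_MIN + 1)
        return pd.DataFrame({"year": years, "age": ages, "count": self._counts.ravel()})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def _check_year(self, year: int) -> int:
        if not (YEAR_MIN <= year <= YEAR_MAX):
            raise ValueError(f"year {year} outside projection horizon "
                             f"{YEAR_MIN}-{YEAR_MAX}")
        return year - YEAR_MIN

    def count(self, year: int, age: int) -> float:
        return float(self._counts[self._check_year(year), age])

    def under_risk(self, year: int) -> dict[AgeGroup, float]:
        """Population under risk per age group (ages <6 and >65 excluded)."""
        row = self._counts[self._check_year(year)]
        return {
            g: float(row[lo : hi + 1].sum()) for g, (lo, hi) in AGE_SPANS.items()
        }

    def total_under_risk(self, year: int) -> float:
        return sum(self.under_risk(year).values())


def population_under_risk(
    proj: PopulationProjection, year: int
) -> dict[AgeGroup, float]:
    """Sum single-age counts over each age group's span for one year."""
    return proj.under_risk(year)


@dataclass(frozen=True)
class PrevalenceTable:
    """Age-group prevalences of AR and AA and the seasonal share of cases.

    Defaults are the point values used in the base-case analysis: AR 4.7% /
    16.9% / 17.95% and AA 3.6% / 5.7% / 3.9% for children / adolescents /
    adults, with 60% of cases seasonal.
    """

    ar: Mapping[AgeGroup, float] = field(
        default_factory=lambda: {
            AgeGroup.CHILDREN: 0.047,
            AgeGroup.ADOLESCENTS: 0.169,
            AgeGroup.ADULTS: 0.1795,
        }
    )
    aa: Mapping[AgeGroup, float] = field(
        default_factory=lambda: {
            AgeGroup.CHILDREN: 0.036,
            AgeGroup.ADOLESCENTS: 0.057,
            AgeGroup.ADULTS: 0.039,
        }
    )
    seasonal_share: float = 0.60

    def __post_init__(self) -> None:
        for name, table in (("ar", self.ar), ("aa", self.aa)):
            for g in AgeGroup:
                p = table[g]
                if not (0.0 <= p <= 1.0):
                    raise ValueError(f"{name} prevalence for {g.value} out of [0,1]: {p}")
        if not (0.0 <= self.seasonal_share <= 1.0):
            raise ValueError(f"seasonal share out of [0,1]: {self.seasonal_share}")

    def type_share(self, atype: AllergyType) -> float:
        return self.seasonal_share if atype is AllergyType.SEASONAL else 1 - self.seasonal_share


@dataclass(frozen=True)
class SeveritySplit:
    """Within-severity allocation of prevalent and incident cases.

    ``ar_mild`` is the share of AR-only patients placed in state A (rest B);
    ``aa_mild`` the share of AA patients in state C (rest D); ``onset_mild``
    the share of new cases entering in A (rest B).  The source analysis does
    not report these splits, so they are model parameters (default 50/50).
    """

    ar_mild: float = 0.5
    aa_mild: float = 0.5
    onset_mild: float = 0.5

    def __post_init__(self) -> None:
        for name in ("ar_mild", "aa_mild", "onset_mild"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} out of [0,1]: {v}")


def initial_prevalent_pool(
    proj: PopulationProjection,
    prev: PrevalenceTable,
    base_year: int = 2011,
    split: SeveritySplit = SeveritySplit(),
) -> dict[StratumKey, np.ndarray]:
    """Build the base-year prevalent pool, all assigned to the ST arm.

    Per age group, AA-prevalent persons occupy the asthma states C/D; AR
    prevalence is taken to include them (asthma patients overwhelmingly also
    have rhinitis), so the AR-only count placed in states A/B is
    ``AR - AA`` (floored at zero).  Each group is split into seasonal and
    perennial allergy types by the seasonal share.  Immunotherapy uptake is
    applied later by the scenario allocation, so everyone starts in ST.
    """
    pool: dict[StratumKey, np.ndarray] = {}
    under_risk = proj.under_risk(base_year)
    for group in AgeGroup:
        n = under_risk[group]
        aa_n = n * prev.aa[group]
        ar_only_n = max(n * prev.ar[group] - aa_n, 0.0)
        base = np.zeros(N_STATES)
        base[DiseaseState.A] = ar_only_n * split.ar_mild
        base[DiseaseState.B] = ar_only_n * (1 - split.ar_mild)
        base[DiseaseState.C] = aa_n * split.aa_mild
        base[DiseaseState.D] = aa_n * (1 - split.aa_mild)
        for atype in AllergyType:
            pool[st_stratum(group, atype)] = base * prev.type_share(atype)
    return pool


#: Uniform-age outflow fractions used to move cohorts between age groups.
AGEING_OUTFLOW = {
    AgeGroup.CHILDREN: 1.0 / age_span_width(AgeGroup.CHILDREN),      # 1/7
    AgeGroup.ADOLESCENTS: 1.0 / age_span_width(AgeGroup.ADOLESCENTS),  # 1/6
    AgeGroup.ADULTS: 1.0 / age_span_width(AgeGroup.ADULTS),          # 1/47
}
_NEXT_GROUP = {AgeGroup.CHILDREN: AgeGroup.ADOLESCENTS, AgeGroup.ADOLESCENTS: AgeGroup.ADULTS}


def age_cohorts(
    cohorts: Mapping[StratumKey, np.ndarray]
) -> dict[StratumKey, np.ndarray]:
    """Move one year's worth of cohort mass between age groups.

    Uniform-age approximation: each year 1/7 of children become adolescents,
    1/6 of adolescents become adults, and 1/47 of adults age out of the
    population under risk (all states alike, including E and F).  Totals are
    conserved apart from the adult outflow.
    """
    out: dict[StratumKey, np.ndarray] = {
        k: validate_cohort(v).copy() for k, v in cohorts.items()
    }
    for key in list(cohorts.keys()):
        frac = AGEING_OUTFLOW[key.age_group]
        moving = np.asarray(cohorts[key], dtype=float) * frac
        out[key] = out[key] - moving
        nxt = _NEXT_GROUP.get(key.age_group)
        if nxt is not None:
            nkey = key.with_age_group(nxt)
            out[nkey] = out.get(nkey, np.zeros(N_STATES)) + moving
    # clip tiny negatives from floating-point cancellation
    return {k: np.clip(v, 0.0, None) for k, v in out.items()}


@dataclass
class IncidenceSchedule:
    """Yearly incident entrant cohorts: year -> stratum -> state vector."""

    entrants: dict[int, dict[StratumKey, np.ndarray]]

    def total(self, year: int) -> float:
        return float(sum(v.sum() for v in self.entrants.get(year, {}).values()))

    def for_year(self, year: int) -> dict[StratumKey, np.ndarray]:
        return self.entrants.get(year, {})

    def scaled(self, factors: Mapping[int, float]) -> "IncidenceSchedule":
        return IncidenceSchedule(
            {
                y: {k: v * factors.get(y, 1.0) for k, v in strata.items()}
                for y, strata in self.entrants.items()
            }
        )


def entrant_template(
    prev: PrevalenceTable, split: SeveritySplit = SeveritySplit()
) -> dict[StratumKey, np.ndarray]:
    """Unit entrant cohort (total 1 person) for one year.

    New cases enter at the youngest modelled ages (the children group) in the
    mild rhinitis states A/B, arm ST, split across allergy types by the
    seasonal share.
    """
    template: dict[StratumKey, np.ndarray] = {}
    base = np.zeros(N_STATES)
    base[DiseaseState.A] = split.onset_mild
    base[DiseaseState.B] = 1 - split.onset_mild
    for atype in AllergyType:
        template[st_stratum(AgeGroup.CHILDREN, atype)] = base * prev.type_share(atype)
    return template


def diseased_total(cohorts: Mapping[StratumKey, np.ndarray]) -> float:
    """Persons in the diseased states A-D, summed over all strata."""
    idx = [int(s) for s in (DiseaseState.A, DiseaseState.B, DiseaseState.C, DiseaseState.D)]
    return float(sum(np.asarray(v)[idx].sum() for v in cohorts.values()))


def calibrate_incidence(
    proj: PopulationProjection,
    run_baseline: Callable[[IncidenceSchedule], "pd.Series"],
    template: Mapping[StratumKey, np.ndarray],
    base_year: int = 2011,
    horizon_end: int = 2050,
    rel_tol: float = 0.005,
    max_iter: int = 100,
) -> IncidenceSchedule:
    """Calibrate yearly entrant counts to the demographic trend.

    Finds entrant totals such that, under the no-SCIT baseline run supplied
    as a callable (``IncidenceSchedule -> diseased totals per year``), the
    diseased total in year y relative to the base year equals the population
    under risk in y relative to the base year, within ``rel_tol``.

    Uses fixed-point iteration: an entrant in year y contributes one diseased
    person to the year-y census, so each sweep adds the current shortfall to
    that year's entrant total (floored at zero, Gauss-Seidel style through
    the triangular year coupling).
    """
    if rel_tol <= 0:
        raise ValueError("rel_tol must be > 0 (exact calibration is unattainable)")
    years = range(base_year + 1, horizon_end + 1)
    pur0 = proj.total_under_risk(base_year)
    baseline0 = run_baseline(IncidenceSchedule({}))
    d0 = float(baseline0.loc[base_year])
    if d0 <= 0:
        # nothing to calibrate against; an empty pool stays empty
        return IncidenceSchedule({y: {} for y in years})
    targets = {y: d0 * proj.total_under_risk(y) / pur0 for y in years}

    totals = {y: 0.0 for y in years}
    for _ in range(max_iter):
        schedule = IncidenceSchedule(
            {y: {k: v * totals[y] for k, v in template.items()} for y in years}
        )
        observed = run_baseline(schedule)
        rel_err = max(abs(observed.loc[y] - targets[y]) / targets[y] for y in years)
        if rel_err <= rel_tol:
            return schedule
        for y in years:
            totals[y] = max(0.0, totals[y] + targets[y] - float(observed.loc[y]))
    raise RuntimeError(
        f"incidence calibration did not converge within {max_iter} iterations "
        f"(last max relative error {rel_err:.4g} > tolerance {rel_tol:g})"
    )
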