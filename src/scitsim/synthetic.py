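"""Synthetic stand-ins for the unpublished model inputs.

Two inputs of the original analysis were never published: the Federal
Statistical Office population projection actually used, and the stratum
transition probabilities (referenced to earlier literature).  This module
generates both with controllable structure so the full pipeline is testable
end-to-end.  Everything produced here is tagged ``provenance: "synthetic"``;
no output of a run built on these inputs represents the original data.
"""

from __future__ import annotations

import numpy as np

from .markov import validate_matrix
from .population import YEAR_MAX, YEAR_MIN, AGE_MAX, PopulationProjection
from .states import (
    N_STATES,
    AgeGroup,
    AllergyType,
    Arm,
    DiseaseState,
)

__all__ = [
    "generate_population_projection",
    "default_transition_params",
    "make_fixture_config",
    "PROVENANCE",
]

PROVENANCE = "synthetic"

_N_YEARS = YEAR_MAX - YEAR_MIN + 1
_N_AGES = AGE_MAX + 1
_YOUTH_EXTRA_TREND = -0.004  # additional yearly decline of ages 0-18 before rescaling


def generate_population_projection(
    base_pop_6_65: float = 62_000_000.0,
    annual_trend: float = -0.003,
    age_profile: str = "flat",
    seed: int | None = 0,
) -> PopulationProjection:
    """Generate a full 2011-2050 x age 0-100 projection table.

    The population under risk (ages 6-65) follows an exact geometric path
    ``base * (1 + annual_trend)**(year - 2011)``.  With the
    ``youth-declining`` profile the share of ages 0-18 shrinks relative to
    adults over time (each year's table is rescaled so the under-risk total
    stays on the geometric path).  A seed adds small reproducible per-cell
    noise; the yearly rescaling keeps the under-risk totals exact.
    """
    if base_pop_6_65 <= 0:
        raise ValueError(f"base population must be positive, got {base_pop_6_65}")
    if abs(annual_trend) > 0.05:
        raise ValueError(f"|annual_trend| must be <= 0.05, got {annual_trend}")
    if age_profile not in ("flat", "youth-declining"):
        raise ValueError(f"unknown age_profile {age_profile!r}")

    per_age = base_pop_6_65 / 60.0  # ages 6..65 inclusive
    years = np.arange(_N_YEARS)[:, None]
    counts = np.full((_N_YEARS, _N_AGES), per_age) * (1.0 + annual_trend) ** years
    if age_profile == "youth-declining":
        ages = np.arange(_N_AGES)[None, :]
        youth = (ages <= 18).astype(float)
        counts *= (1.0 + _YOUTH_EXTRA_TREND) ** (years * youth)
    if seed is not None:
        rng = np.random.default_rng(seed)
        counts *= 1.0 + rng.uniform(-0.01, 0.01, size=counts.shape)
    # rescale every year so the 6-65 total sits exactly on the geometric path
    targets = base_pop_6_65 * (1.0 + annual_trend) ** np.arange(_N_YEARS)
    risk_sums = counts[:, 6:66].sum(axis=1)
    counts *= (targets / risk_sums)[:, None]
    return PopulationProjection(counts)


# Base yearly probabilities under symptomatic therapy (adults, seasonal).
# rows A-D: remission to E, progression one severity step, improvement one
# step; E: relapse to A.  Mortality is added per age group on top.
_BASE_REMISSION = {DiseaseState.A: 0.06, DiseaseState.B: 0.04,
                   DiseaseState.C: 0.02, DiseaseState.D: 0.01}
_BASE_PROGRESSION = {DiseaseState.A: 0.10, DiseaseState.B: 0.06, DiseaseState.C: 0.05}
_BASE_IMPROVEMENT = {DiseaseState.B: 0.06, DiseaseState.C: 0.05, DiseaseState.D: 0.05}
_BASE_RELAPSE = 0.02

_MORTALITY = {AgeGroup.CHILDREN: 0.0003, AgeGroup.ADOLESCENTS: 0.0005,
              AgeGroup.ADULTS: 0.004}
# younger patients remit more readily; perennial disease is more persistent
_REMISSION_AGE_FACTOR = {AgeGroup.CHILDREN: 1.5, AgeGroup.ADOLESCENTS: 1.2,
                         AgeGroup.ADULTS: 1.0}
_PERENNIAL_REMISSION_FACTOR = 0.8
_PERENNIAL_PROGRESSION_FACTOR = 1.1

# SCIT effect scaling: remission x (1 + 4*s), progression x (1 - 0.9*s)
_SCIT_REMISSION_GAIN = 4.0
_SCIT_PROGRESSION_REDUCTION = 0.9


def _build_matrix(
    group: AgeGroup,
    atype: AllergyType,
    arm: Arm,
    effect_size: float,
    rng: np.random.Generator | None,
    jitter: float,
) -> np.ndarray:
    rem_f = _REMISSION_AGE_FACTOR[group]
    prog_f = 1.0
    if atype is AllergyType.PERENNIAL:
        rem_f *= _PERENNIAL_REMISSION_FACTOR
        prog_f *= _PERENNIAL_PROGRESSION_FACTOR
    if arm is Arm.SCIT:
        rem_f *= 1.0 + _SCIT_REMISSION_GAIN * effect_size
        prog_f *= 1.0 - _SCIT_PROGRESSION_REDUCTION * effect_size
    mort = _MORTALITY[group]

    m = np.zeros((N_STATES, N_STATES))
    order = [DiseaseState.A, DiseaseState.B, DiseaseState.C, DiseaseState.D]
    for i, s in enumerate(order):
        m[s, DiseaseState.E] = _BASE_REMISSION[s] * rem_f
        if s in _BASE_PROGRESSION:
            m[s, order[i + 1]] = _BASE_PROGRESSION[s] * prog_f
        if s in _BASE_IMPROVEMENT:
            m[s, order[i - 1]] = _BASE_IMPROVEMENT[s]
    m[DiseaseState.E, DiseaseState.A] = _BASE_RELAPSE
    m[:5, DiseaseState.F] = mort
    if rng is not None and jitter > 0:
        off = m > 0
        m[off] *= 1.0 + rng.uniform(-jitter, jitter, size=int(off.sum()))
        m = np.clip(m, 0.0, None)
    for i in range(5):
        m[i, i] = 1.0 - m[i].sum()
        if m[i, i] < 0:
            raise ValueError(
                f"synthetic matrix row {DiseaseState(i).name} over-allocated "
                f"({group.value}/{atype.value}/{arm.value})"
            )
    m[DiseaseState.F, DiseaseState.F] = 1.0
    return m


def default_transition_params(
    effect_size: float = 0.75,
    seed: int | None = None,
    jitter: float = 0.0,
) -> dict[tuple[AgeGroup, AllergyType, Arm], np.ndarray]:
    """Synthetic yearly transition matrices for all 12 (group, type, arm) strata.

    These are NOT published values; they are plausible placeholders obeying
    the qualitative structure of the disease model: from every symptomatic
    state both worsening and improvement (including remission to the healthy
    state E) are possible, every row carries a small absorbing death
    probability, and SCIT matrices have uniformly higher remission and lower
    progression than their symptomatic-therapy counterparts, with the gap
    scaling linearly in ``effect_size`` (0 makes SCIT identical to ST).
    ``jitter`` adds seeded multiplicative noise to the non-zero off-diagonal
    entries (used by the probabilistic analysis; 0 keeps the matrices exact).
    """
    if not (0.0 <= effect_size <= 1.0):
        raise ValueError(f"effect_size must be in [0,1], got {effect_size}")
    if jitter < 0 or jitter >= 0.5:
        raise ValueError(f"jitter must be in [0, 0.5), got {jitter}")
    rng = np.random.default_rng(seed) if (seed is not None and jitter > 0) else None
    out: dict[tuple[AgeGroup, AllergyType, Arm], np.ndarray] = {}
    for group in AgeGroup:
        for atype in AllergyType:
            for arm in (Arm.ST, Arm.SCIT):
                out[(group, atype, arm)] = _build_matrix(
                    group, atype, arm, effect_size, rng, jitter
                )
    _self_check(out, effect_size)
    return out


def _self_check(
    matrices: dict[tuple[AgeGroup, AllergyType, Arm], np.ndarray], effect_size: float
) -> None:
    e, f = int(DiseaseState.E), int(DiseaseState.F)
    for key, m in matrices.items():
        validate_matrix(m)
        if np.any(m[:5, f] <= 0):
            raise AssertionError(f"missing death probability in {key}")
    for group in AgeGroup:
        for atype in AllergyType:
            st = matrices[(group, atype, Arm.ST)]
            sc = matrices[(group, atype, Arm.SCIT)]
            if np.any(sc[:4, e] < st[:4, e] - 1e-12):
                raise AssertionError(f"SCIT remission below ST for {group}/{atype}")
            prog_pairs = [(0, 1), (1, 2), (2, 3)]
            for i, j in prog_pairs:
                if sc[i, j] > st[i, j] + 1e-12:
                    raise AssertionError(f"SCIT progression above ST for {group}/{atype}")
            if effect_size == 0 and not np.allclose(st, sc):
                raise AssertionError("effect_size 0 must make SCIT identical to ST")


def make_fixture_config(scale: str = "desk", seed: int = 0):
    """Complete, self-contained run configurations for testing and demos.

    ``desk`` is the full analysis: 2011-2050 horizon, all strata, the
    base-case point values for prevalences, costs and discounting, a mildly
    declining youth-heavy synthetic population, and the synthetic default
    matrices.  ``toy`` is a hand-checkable miniature: a 3-year horizon and a
    tiny flat population, with prevalence zeroed outside the children group
    so only two strata are populated.
    """
    from .config import CalibrationSpec, PopulationSource, RunConfig, TransitionSource
    from .population import PrevalenceTable

    if scale == "desk":
        return RunConfig(
            population=PopulationSource(
                kind="synthetic",
                base_pop_6_65=62_000_000.0,
                annual_trend=-0.003,
                age_profile="youth-declining",
                seed=seed,
            ),
            transitions=TransitionSource(kind="synthetic", effect_size=0.75,
                                         jitter=0.0, seed=seed),
        )
    if scale == "toy":
        prevalence = PrevalenceTable(
            ar={AgeGroup.CHILDREN: 0.10, AgeGroup.ADOLESCENTS: 0.0,
                AgeGroup.ADULTS: 0.0},
            aa={AgeGroup.CHILDREN: 0.04, AgeGroup.ADOLESCENTS: 0.0,
                AgeGroup.ADULTS: 0.0},
            seasonal_share=0.60,
        )
        return RunConfig(
            population=PopulationSource(
                kind="synthetic", base_pop_6_65=60_000.0, annual_trend=0.0,
                age_profile="flat", seed=seed,
            ),
            prevalence=prevalence,
            transitions=TransitionSource(kind="synthetic", effect_size=0.75,
                                         jitter=0.0, seed=seed),
            calibration=CalibrationSpec(rel_tol=0.005, max_iter=100),
            horizon=(2011, 2013),
        )
    raise ValueError(f"unknown fixture scale {scale!r}; use 'toy' or 'desk'")
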