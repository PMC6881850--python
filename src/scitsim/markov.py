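"""Markov cohort propagation: row-stochastic matrices and yearly cycles.

A transition matrix is a 6x6 array of yearly probabilities indexed
(from-state, to-state) in the fixed state order (A, B, C, D, E, F).  Cohort
vectors hold expected (real-valued) person-counts per state; propagating one
cycle is a vector-matrix product, which conserves total persons because every
row sums to one.  Death (state F) must be absorbing.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

from .states import N_STATES, DiseaseState, StratumKey

__all__ = ["validate_matrix", "validate_cohort", "advance_cycle", "advance_stratified"]

_ROW_SUM_TOL = 1e-9


def validate_matrix(m: np.ndarray) -> np.ndarray:
    """Validate a 6x6 yearly transition matrix and return it as a float array.

    Raises ``ValueError`` naming the offending row if any row sum deviates
    from 1 by more than 1e-9, if any entry is negative or non-finite, or if
    row F is not the unit vector on F (death not absorbing).
    """
    a = np.asarray(m, dtype=float)
    if a.shape != (N_STATES, N_STATES):
        raise ValueError(f"transition matrix must be {N_STATES}x{N_STATES}, got {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError("transition matrix contains non-finite entries")
    neg = np.argwhere(a < 0)
    if neg.size:
        i, j = neg[0]
        raise ValueError(
            f"negative transition probability {a[i, j]:g} at "
            f"({DiseaseState(i).name} -> {DiseaseState(j).name})"
        )
    if np.any(a > 1 + _ROW_SUM_TOL):
        i, j = np.argwhere(a > 1 + _ROW_SUM_TOL)[0]
        raise ValueError(
            f"transition probability {a[i, j]:g} > 1 at "
            f"({DiseaseState(i).name} -> {DiseaseState(j).name})"
        )
    sums = a.sum(axis=1)
    bad = np.where(np.abs(sums - 1.0) > _ROW_SUM_TOL)[0]
    if bad.size:
        i = int(bad[0])
        raise ValueError(
            f"row {DiseaseState(i).name} (index {i}) sums to {sums[i]:.12g}, expected 1"
        )
    f = int(DiseaseState.F)
    expected_f = np.zeros(N_STATES)
    expected_f[f] = 1.0
    if not np.array_equal(a[f] != 0, expected_f != 0) or abs(a[f, f] - 1.0) > _ROW_SUM_TOL:
        raise ValueError("death is not absorbing: row F must be (0, 0, 0, 0, 0, 1)")
    return a


def validate_cohort(v: np.ndarray) -> np.ndarray:
    """Validate a length-6 cohort vector of non-negative person-counts."""
    a = np.asarray(v, dtype=float)
    if a.shape != (N_STATES,):
        raise ValueError(f"cohort vector must have length {N_STATES}, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError("cohort vector contains non-finite counts")
    if np.any(a < 0):
        i = int(np.argwhere(a < 0)[0][0])
        raise ValueError(f"negative count {a[i]:g} in state {DiseaseState(i).name}")
    return a


def advance_cycle(v: np.ndarray, m: np.ndarray) -> np.ndarray:
    """Propagate a cohort vector one yearly cycle: out[j] = sum_i v[i] * m[i, j]."""
    v = np.asarray(v, dtype=float)
    m = np.asarray(m, dtype=float)
    if v.shape != (N_STATES,) or m.shape != (N_STATES, N_STATES):
        raise ValueError(
            f"dimension mismatch: vector {v.shape} vs matrix {m.shape}; expected "
            f"({N_STATES},) and ({N_STATES}, {N_STATES})"
        )
    return v @ m


def advance_stratified(
    cohorts: Mapping[StratumKey, np.ndarray],
    matrices: Mapping[StratumKey, np.ndarray],
) -> dict[StratumKey, np.ndarray]:
    """Advance every stratum independently by one cycle.

    Every stratum present in ``cohorts`` must have a matrix; a missing matrix
    is an error, never a silent skip.
    """
    missing = [k for k in cohorts if k not in matrices]
    if missing:
        raise KeyError(f"no transition matrix for strata: {[str(k) for k in missing]}")
    return {k: advance_cycle(v, matrices[k]) for k, v in cohorts.items()}
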