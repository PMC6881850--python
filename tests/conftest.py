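import numpy as np
import pytest

import scitsim as ss
from scitsim.states import N_STATES, DiseaseState


def random_valid_matrix(rng: np.random.Generator, min_death: float = 0.0) -> np.ndarray:
    """Random row-stochastic 6x6 matrix with absorbing death."""
    m = rng.dirichlet(np.ones(N_STATES), size=N_STATES)
    if min_death > 0:
        m[:, int(DiseaseState.F)] = np.maximum(m[:, int(DiseaseState.F)], min_death)
        m /= m.sum(axis=1, keepdims=True)
    m[int(DiseaseState.F)] = 0.0
    m[int(DiseaseState.F), int(DiseaseState.F)] = 1.0
    return m


@pytest.fixture
def rng():
    return np.random.default_rng(20110101)


@pytest.fixture(scope="session")
def toy_config():
    return ss.make_fixture_config("toy", seed=0)


@pytest.fixture(scope="session")
def desk_config():
    return ss.make_fixture_config("desk", seed=0)


@pytest.fixture(scope="session")
def desk_prepared(desk_config):
    return ss.prepare(desk_config)


@pytest.fixture(scope="session")
def desk_results(desk_prepared):
    return ss.run_scenarios(desk_prepared)
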