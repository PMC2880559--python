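import numpy as np
import pytest

from workloop import (
    OptimalControlProblem,
    default_load_params,
    default_muscle_params,
    solve_cyclic_optimal_control,
)


@pytest.fixture(scope="session")
def muscle():
    return default_muscle_params()


@pytest.fixture(scope="session")
def load():
    return default_load_params()


@pytest.fixture(scope="session")
def single_muscles(muscle):
    return (muscle, muscle.zeroed())


@pytest.fixture(scope="session")
def pair_muscles(muscle):
    return (muscle, muscle)


@pytest.fixture(scope="session")
def solution_single_24(single_muscles, load):
    """Converged cyclic optimum of the single-muscle system at 2.4 Hz."""
    problem = OptimalControlProblem(muscles=single_muscles, load=load, frequency=2.4)
    sol = solve_cyclic_optimal_control(problem)
    assert sol.converged
    return sol


@pytest.fixture(scope="session")
def solution_pair_25(pair_muscles, load):
    """Converged cyclic optimum of the muscle-pair system at 2.5 Hz."""
    problem = OptimalControlProblem(muscles=pair_muscles, load=load, frequency=2.5)
    sol = solve_cyclic_optimal_control(problem)
    assert sol.converged
    return sol


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
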