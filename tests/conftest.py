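import numpy as np
import pytest

from vitiflux import (
    FluxProblem,
    assemble_problem,
    build_gt3_network,
    minimize_flux,
    study_measurements,
)


@pytest.fixture(scope="session")
def gt3():
    return build_gt3_network()


@pytest.fixture
def fork_problem():
    """r1 -> A fixed at 2; r2, r3 drain A; all irreversible, unit weights."""
    return FluxProblem(
        S=np.array([[1.0, -1.0, -1.0]]),
        lb=np.array([2.0, 0.0, 0.0]),
        ub=np.array([2.0, np.inf, np.inf]),
        reaction_ids=["r1", "r2", "r3"],
    )


@pytest.fixture
def capped_fork_problem():
    """Same fork with an enzyme capacity of 0.5 on r2."""
    return FluxProblem(
        S=np.array([[1.0, -1.0, -1.0]]),
        lb=np.array([2.0, 0.0, 0.0]),
        ub=np.array([2.0, 0.5, np.inf]),
        reaction_ids=["r1", "r2", "r3"],
    )


@pytest.fixture
def infeasible_problem():
    """A is produced at a fixed positive rate but nothing consumes it."""
    return FluxProblem(
        S=np.array([[1.0]]),
        lb=np.array([1.5]),
        ub=np.array([1.5]),
        reaction_ids=["r1"],
    )


@pytest.fixture(scope="session")
def study_solutions(gt3):
    """Solved day-4 flux maps for the control and low-N study tables."""
    out = {}
    for cond in ("N", "N-"):
        ms = study_measurements(cond)
        problem = assemble_problem(gt3, ms, 4.0)
        solution = minimize_flux(problem)
        assert solution.ok, f"study condition {cond} must solve"
        out[cond] = (problem, solution)
    return out
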