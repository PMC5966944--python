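"""Quadratic flux minimization: solver, oracle, KKT checks, diagnosis."""

import numpy as np
import pytest

from vitiflux import (
    FluxProblem,
    check_kkt,
    diagnose_infeasibility,
    minimize_flux,
    solve_oracle_small,
)
from vitiflux.synth import random_small_problem


def test_fork_splits_symmetrically(fork_problem):
    sol = minimize_flux(fork_problem)
    assert sol.ok
    assert sol.v == pytest.approx([2.0, 1.0, 1.0], abs=1e-9)
    assert sol.objective == pytest.approx(6.0)


def test_capacity_redirects_the_split(capped_fork_problem):
    sol = minimize_flux(capped_fork_problem)
    assert sol.v == pytest.approx([2.0, 0.5, 1.5], abs=1e-9)


def test_oracle_agrees_on_forks(fork_problem, capped_fork_problem):
    for p in (fork_problem, capped_fork_problem):
        assert solve_oracle_small(p).v == pytest.approx(minimize_flux(p).v,
                                                        abs=1e-9)


def test_fully_fixed_problem_returns_the_point():
    p = FluxProblem(S=np.array([[1.0, -1.0]]), lb=np.array([1.0, 1.0]),
                    ub=np.array([1.0, 1.0]), reaction_ids=["a", "b"])
    for solver in (minimize_flux, solve_oracle_small):
        sol = solver(p)
        assert sol.ok and sol.v == pytest.approx([1.0, 1.0])


def test_infeasible_is_certified_not_approximated(infeasible_problem):
    for solver in (minimize_flux, solve_oracle_small):
        sol = solver(infeasible_problem)
        assert sol.status == "infeasible"
        assert sol.v is None


def test_weights_skew_the_split(fork_problem):
    p = fork_problem
    p2 = FluxProblem(S=p.S, lb=p.lb, ub=p.ub, reaction_ids=p.reaction_ids,
                     weights=np.array([1.0, 4.0, 1.0]))
    sol = minimize_flux(p2)
    # stationarity: w2*v2 = w3*v3 -> v2 = v3/4, v2+v3 = 2
    assert sol.v == pytest.approx([2.0, 0.4, 1.6], abs=1e-9)
    assert solve_oracle_small(p2).v == pytest.approx(sol.v, abs=1e-9)


def test_oracle_refuses_large_problems():
    rng = np.random.default_rng(0)
    p = random_small_problem(rng, n_reactions=14, n_metabolites=4)
    with pytest.raises(ValueError):
        solve_oracle_small(p)


def test_random_problems_match_oracle():
    rng = np.random.default_rng(2024)
    n_feasible = 0
    for _ in range(60):
        p = random_small_problem(rng)
        sol = minimize_flux(p)
        oracle = solve_oracle_small(p)
        assert sol.status == oracle.status
        if oracle.ok:
            n_feasible += 1
            scale = 1.0 + np.max(np.abs(oracle.v))
            assert np.max(np.abs(sol.v - oracle.v)) / scale < 1e-6
    assert n_feasible >= 20  # the generator must produce solvable instances


def test_osqp_cross_check():
    """Independent QP solver agrees on random feasible instances."""
    osqp = pytest.importorskip("osqp")
    import scipy.sparse as sp

    rng = np.random.default_rng(5)
    checked = 0
    while checked < 10:
        p = random_small_problem(rng)
        sol = minimize_flux(p)
        if not sol.ok:
            continue
        n = p.n
        A_rows = [p.S]
        lo = [np.zeros(p.S.shape[0])]
        hi = [np.zeros(p.S.shape[0])]
        if p.couplings is not None:
            A_rows.append(p.couplings)
            lo.append(p.coupling_rhs)
            hi.append(p.coupling_rhs)
        A_rows.append(np.eye(n))
        lo.append(p.lb)
        hi.append(p.ub)
        m = osqp.OSQP()
        m.setup(P=sp.csc_matrix(np.diag(2.0 * p.weights)), q=np.zeros(n),
                A=sp.csc_matrix(np.vstack(A_rows)),
                l=np.concatenate(lo), u=np.concatenate(hi),
                eps_abs=1e-10, eps_rel=1e-10, polish=True, verbose=False,
                max_iter=200000)
        res = m.solve()
        if "solved" not in res.info.status:
            continue
        assert np.max(np.abs(res.x - sol.v)) < 1e-4
        checked += 1


# ---------------------------------------------------------------------------
# KKT verification
# ---------------------------------------------------------------------------

def test_kkt_clean_at_fork_optimum(fork_problem):
    sol = minimize_flux(fork_problem)
    report = check_kkt(fork_problem, sol, tol=1e-8)
    assert report.ok
    assert report.stationarity <= 1e-8
    assert report.primal_balance <= 1e-8


def test_kkt_detects_a_broken_optimum(fork_problem):
    sol = minimize_flux(fork_problem)
    sol.v = sol.v.copy()
    sol.v[1] += 0.1
    sol.v[2] -= 0.1  # keep the balance, break stationarity
    report = check_kkt(fork_problem, sol, tol=1e-8)
    assert not report.ok
    assert report.stationarity > 1e-8


def test_kkt_bound_multiplier_sign_at_capacity(capped_fork_problem):
    sol = minimize_flux(capped_fork_problem)
    report = check_kkt(capped_fork_problem, sol, tol=1e-8)
    assert report.ok
    assert report.sign_violation <= 1e-8


# ---------------------------------------------------------------------------
# infeasibility diagnosis
# ---------------------------------------------------------------------------

def test_elastic_diagnosis_names_the_dead_end(infeasible_problem):
    report = diagnose_infeasibility(infeasible_problem)
    assert len(report.entries) == 1
    label, slack = report.entries[0]
    assert label == "r1"
    assert slack == pytest.approx(-1.5, abs=1e-6)


def test_feasible_problem_yields_empty_report(fork_problem):
    assert diagnose_infeasibility(fork_problem).empty


def test_excessive_respiration_coupling_is_flagged():
    # A -> B at most 1 (capacity), but the coupling row demands r1 = 3
    p = FluxProblem(
        S=np.array([[1.0, -1.0]]),
        lb=np.array([0.0, 0.0]), ub=np.array([1.0, np.inf]),
        reaction_ids=["r1", "r2"],
        couplings=np.array([[1.0, 0.0]]), coupling_rhs=np.array([3.0]))
    assert minimize_flux(p).status == "infeasible"
    report = diagnose_infeasibility(p)
    assert report.entries
    assert report.entries[0][0].startswith("coupling")


# ---------------------------------------------------------------------------
# solver properties
# ---------------------------------------------------------------------------

def test_uniqueness_under_permutation():
    rng = np.random.default_rng(99)
    for _ in range(10):
        p = random_small_problem(rng)
        sol = minimize_flux(p)
        if not sol.ok:
            continue
        order = rng.permutation(p.n)
        sol_p = minimize_flux(p.permuted(order))
        assert np.max(np.abs(np.asarray(sol_p.v) - np.asarray(sol.v)[order])) < 1e-6


@pytest.mark.parametrize("lam", [0.5, 2.0, 10.0])
def test_scale_equivariance(lam, capped_fork_problem):
    base = minimize_flux(capped_fork_problem)
    scaled = minimize_flux(capped_fork_problem.scaled(lam))
    assert np.max(np.abs(scaled.v - lam * base.v)) <= 1e-8 * lam * (
        1 + np.max(np.abs(base.v)))


def test_relaxing_a_bound_never_raises_the_objective():
    rng = np.random.default_rng(31)
    relaxed_checked = 0
    while relaxed_checked < 10:
        p = random_small_problem(rng)
        sol = minimize_flux(p)
        if not sol.ok:
            continue
        finite = [j for j in range(p.n)
                  if np.isfinite(p.ub[j]) and p.lb[j] < p.ub[j]]
        if not finite:
            continue
        j = finite[0]
        ub2 = p.ub.copy()
        ub2[j] = np.inf
        p2 = FluxProblem(S=p.S, lb=p.lb, ub=ub2, reaction_ids=p.reaction_ids,
                         weights=p.weights, couplings=p.couplings,
                         coupling_rhs=p.coupling_rhs)
        sol2 = minimize_flux(p2)
        assert sol2.ok
        assert sol2.objective <= sol.objective + 1e-9 * (1 + sol.objective)
        relaxed_checked += 1


def test_l1_objective_variant(fork_problem):
    sol = minimize_flux(fork_problem, objective="l1")
    assert sol.ok
    # any split of the fixed inflow across r2/r3 has the same L1 norm
    assert sol.objective == pytest.approx(4.0, abs=1e-9)
    assert sol.v[1] + sol.v[2] == pytest.approx(2.0, abs=1e-9)
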