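"""Quadratic flux minimization.

Solves

    min  sum_i w_i v_i^2
    s.t. S v = 0                  (steady-state mass balance)
         C v  = r  (or in [r_lo, r_hi])   (extra coupling rows)
         lb <= v <= ub

with strictly positive weights, so the objective is strictly convex and
the minimizer — when the constraint set is non-empty — is unique. This
is the "flux minimization" resolution principle: among all steady-state
flux distributions consistent with the data, pick the one of least
total squared flux.

The solver is a primal active-set method on the bound constraints:
equality-constrained subproblems are solved exactly through their KKT
systems, so optimal solutions satisfy the mass balance to machine
precision rather than to an iterative solver's tolerance. A phase-1
linear program (scipy/HiGHS) supplies the feasible starting point and
certifies infeasibility.

Interval couplings are handled by a slack variable carrying zero
objective weight; the flux part of the solution remains unique.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy.optimize import linprog

__all__ = [
    "FluxProblem",
    "FluxSolution",
    "KKTReport",
    "RelaxationReport",
    "minimize_flux",
    "solve_oracle_small",
    "check_kkt",
    "diagnose_infeasibility",
    "write_solution_tsv",
]

_FEAS_TOL = 1e-9
_OPT_TOL = 1e-8


@dataclass
class FluxProblem:
    """Bound- and balance-constrained flux minimization instance.

    ``S`` has one row per balanced (internal) metabolite and one column
    per reaction, ordered like ``reaction_ids``. ``couplings`` is a
    (k, n) array of extra linear rows with right-hand sides
    ``coupling_rhs``; when ``coupling_lo``/``coupling_hi`` are given the
    rows are interval constraints instead of equalities.
    """

    S: np.ndarray
    lb: np.ndarray
    ub: np.ndarray
    reaction_ids: list[str]
    weights: np.ndarray | None = None
    couplings: np.ndarray | None = None
    coupling_rhs: np.ndarray | None = None
    coupling_lo: np.ndarray | None = None
    coupling_hi: np.ndarray | None = None
    metabolite_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.S = np.atleast_2d(np.asarray(self.S, dtype=float))
        self.lb = np.asarray(self.lb, dtype=float)
        self.ub = np.asarray(self.ub, dtype=float)
        n = self.S.shape[1]
        if self.weights is None:
            self.weights = np.ones(n)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.couplings is not None:
            self.couplings = np.atleast_2d(np.asarray(self.couplings, dtype=float))
            if self.coupling_rhs is not None:
                self.coupling_rhs = np.atleast_1d(
                    np.asarray(self.coupling_rhs, dtype=float))
        self.validate()

    @property
    def n(self) -> int:
        return self.S.shape[1]

    @property
    def n_couplings(self) -> int:
        return 0 if self.couplings is None else self.couplings.shape[0]

    def validate(self) -> None:
        n = self.n
        for name, arr in (("lb", self.lb), ("ub", self.ub), ("weights", self.weights)):
            if arr.shape != (n,):
                raise ValueError(f"{name} has shape {arr.shape}, expected ({n},)")
        if len(self.reaction_ids) != n:
            raise ValueError("reaction_ids length does not match S columns")
        bad = [self.reaction_ids[i] for i in np.flatnonzero(self.lb > self.ub)]
        if bad:
            raise ValueError(f"lb > ub for reactions: {bad}")
        if not np.all(self.weights > 0):
            raise ValueError("objective weights must be strictly positive")
        if self.couplings is not None:
            if self.couplings.shape[1] != n:
                raise ValueError("coupling rows have wrong width")
            interval = self.coupling_lo is not None or self.coupling_hi is not None
            if interval:
                if self.coupling_lo is None or self.coupling_hi is None:
                    raise ValueError("interval couplings need both lo and hi")
            elif self.coupling_rhs is None:
                raise ValueError("couplings need a right-hand side")

    # -- helpers -------------------------------------------------------
    def scaled(self, lam: float) -> "FluxProblem":
        """Scale all finite bounds and coupling right-hand sides by lam > 0."""

        def sc(a):
            return None if a is None else np.where(np.isfinite(a), a * lam, a)

        return FluxProblem(
            S=self.S.copy(), lb=sc(self.lb), ub=sc(self.ub),
            reaction_ids=list(self.reaction_ids), weights=self.weights.copy(),
            couplings=None if self.couplings is None else self.couplings.copy(),
            coupling_rhs=sc(self.coupling_rhs),
            coupling_lo=sc(self.coupling_lo), coupling_hi=sc(self.coupling_hi),
            metabolite_ids=list(self.metabolite_ids),
        )

    def permuted(self, order: np.ndarray) -> "FluxProblem":
        order = np.asarray(order)
        return FluxProblem(
            S=self.S[:, order], lb=self.lb[order], ub=self.ub[order],
            reaction_ids=[self.reaction_ids[i] for i in order],
            weights=self.weights[order],
            couplings=None if self.couplings is None else self.couplings[:, order],
            coupling_rhs=None if self.coupling_rhs is None else self.coupling_rhs.copy(),
            coupling_lo=None if self.coupling_lo is None else self.coupling_lo.copy(),
            coupling_hi=None if self.coupling_hi is None else self.coupling_hi.copy(),
            metabolite_ids=list(self.metabolite_ids),
        )


@dataclass
class FluxSolution:
    v: np.ndarray | None
    objective: float | None
    status: str  # optimal | infeasible | numerical-failure
    reaction_ids: list[str] = field(default_factory=list)
    balance_residual: float = np.nan
    bound_violation: float = np.nan
    kkt_residual: float = np.nan
    multipliers: dict | None = None

    @property
    def ok(self) -> bool:
        return self.status == "optimal"

    def flux(self, rxn_id: str) -> float:
        return float(self.v[self.reaction_ids.index(rxn_id)])

    def as_dict(self) -> dict:
        return dict(zip(self.reaction_ids, map(float, self.v)))


# ----------------------------------------------------------------------
# internal: equality/bound QP in "augmented" form
# ----------------------------------------------------------------------

def _augmented(problem: FluxProblem):
    """Return (q, A, b, lb, ub, n_slack) with interval couplings slacked.

    Variables are [v; s] where s (one per interval coupling) has zero
    weight and bounds [lo, hi]; rows become C v - s = 0.
    """
    n = problem.n
    q = 2.0 * problem.weights
    A = problem.S
    b = np.zeros(problem.S.shape[0])
    lb, ub = problem.lb.copy(), problem.ub.copy()
    n_slack = 0
    if problem.couplings is not None:
        C = problem.couplings
        if problem.coupling_lo is not None:
            k = C.shape[0]
            n_slack = k
            A = np.block([[A, np.zeros((A.shape[0], k))],
                          [C, -np.eye(k)]])
            b = np.concatenate([b, np.zeros(k)])
            lb = np.concatenate([lb, problem.coupling_lo])
            ub = np.concatenate([ub, problem.coupling_hi])
            q = np.concatenate([q, np.zeros(k)])
        else:
            A = np.vstack([A, C])
            b = np.concatenate([b, problem.coupling_rhs])
    return q, A, b, lb, ub, n_slack


def _solve_eqp(q, A, b):
    """min 1/2 x^T diag(q) x  s.t.  A x = b; q >= 0.

    Solved through the (possibly singular) KKT system with lstsq, which
    returns the minimum-norm solution; for q > 0 on the variables that
    matter the primal part is the unique minimizer. Returns (x, lam,
    consistent) where consistent reflects whether A x = b is attainable.
    """
    m, n = A.shape
    K = np.zeros((n + m, n + m))
    K[:n, :n] = np.diag(q)
    K[:n, n:] = -A.T
    K[n:, :n] = A
    rhs = np.concatenate([np.zeros(n), b])
    sol, *_ = np.linalg.lstsq(K, rhs, rcond=None)
    x, lam = sol[:n], sol[n:]
    consistent = np.linalg.norm(A @ x - b) <= 1e-7 * (1.0 + np.linalg.norm(b))
    return x, lam, consistent


def _phase1(A, b, lb, ub):
    """Feasible point via LP, or None if infeasible."""
    n = A.shape[1]
    res = linprog(c=np.zeros(n), A_eq=A, b_eq=b,
                  bounds=list(zip(lb, ub)), method="highs")
    if res.status != 0 or res.x is None:
        return None
    return np.clip(res.x, lb, ub)


def minimize_flux(problem: FluxProblem, tol: float = _FEAS_TOL,
                  max_iter: int | None = None,
                  objective: str = "quadratic") -> FluxSolution:
    """Solve the flux-minimization problem.

    The default objective is the strictly convex sum of weighted squared
    fluxes, whose minimizer is unique whenever the constraints are
    consistent. ``objective="l1"`` minimizes the weighted sum of
    absolute fluxes instead (the linear form of the flux-minimization
    principle); it is solved as an LP and its minimizer need not be
    unique, so it is offered for comparison only.

    Returns a :class:`FluxSolution` whose status is ``optimal``,
    ``infeasible`` (certified by the phase-1 LP) or
    ``numerical-failure`` (active-set iteration limit; residuals are
    reported, never a silent near-solution).
    """
    problem.validate()
    if objective == "l1":
        return _minimize_flux_l1(problem)
    if objective != "quadratic":
        raise ValueError(f"unknown objective {objective!r}")
    q, A, b, lb, ub, n_slack = _augmented(problem)
    n = len(q)

    # eliminate fixed variables (lb == ub) for conditioning
    fixed = lb == ub
    x_fix = np.where(fixed, lb, 0.0)
    free_idx = np.flatnonzero(~fixed)
    if free_idx.size == 0:
        x = x_fix
        if np.linalg.norm(A @ x - b) > 1e-7 * (1.0 + np.linalg.norm(b)):
            return FluxSolution(v=None, objective=None, status="infeasible",
                                reaction_ids=list(problem.reaction_ids))
        return _finish(problem, x, n_slack, A, b, lb, ub, q, lam=None)

    A_red = A[:, free_idx]
    b_red = b - A[:, fixed] @ x_fix[fixed]
    lb_red, ub_red = lb[free_idx], ub[free_idx]
    q_red = q[free_idx]

    x0 = _phase1(A_red, b_red, lb_red, ub_red)
    if x0 is None:
        return FluxSolution(v=None, objective=None, status="infeasible",
                            reaction_ids=list(problem.reaction_ids))

    x, lam, ok = _active_set(q_red, A_red, b_red, lb_red, ub_red, x0,
                             tol=tol, max_iter=max_iter)
    full = x_fix.copy()
    full[free_idx] = x
    if not ok:
        sol = _finish(problem, full, n_slack, A, b, lb, ub, q, lam=None)
        sol.status = "numerical-failure"
        return sol
    return _finish(problem, full, n_slack, A, b, lb, ub, q, lam=lam)


def _active_set(q, A, b, lb, ub, x0, tol=_FEAS_TOL, max_iter=None):
    """Primal active-set iteration. Returns (x, lam, converged)."""
    n = len(q)
    if max_iter is None:
        max_iter = 50 * (n + 1)
    atol = 1e-10

    x = x0.copy()
    # working set: +1 at upper bound, -1 at lower bound, 0 free
    # (differences, not abs-of-difference, so infinite bounds never match)
    W = np.zeros(n, dtype=int)
    W[x - lb <= atol * (1.0 + np.abs(x))] = -1
    W[ub - x <= atol * (1.0 + np.abs(x))] = +1

    lam = np.zeros(A.shape[0])
    for _ in range(max_iter):
        free = W == 0
        nf = int(free.sum())
        # equality QP on the free block: min 1/2 y' Q y s.t. A_f y = r
        r = b - A[:, ~free] @ x[~free]
        if nf:
            y, lam, _ = _solve_eqp(q[free], A[:, free], r)
            p = np.zeros(n)
            p[free] = y - x[free]
        else:
            # all variables at bounds; multipliers from full gradient
            _, lam, _ = _solve_eqp(q, A, b)  # lam init; refined below
            p = np.zeros(n)
            lam = _bound_multiplier_lam(q, A, x)

        if np.max(np.abs(p)) <= 1e-11 * (1.0 + np.max(np.abs(x))):
            # stationary on the working set; check bound multipliers
            lam = _bound_multiplier_lam(q, A, x, W)
            g = q * x - A.T @ lam
            viol_lo = (W == -1) & (g < -1e-9)
            viol_hi = (W == +1) & (g > 1e-9)
            if not viol_lo.any() and not viol_hi.any():
                return x, lam, True
            # drop the worst offender (ties: lowest index, for determinism)
            score = np.where(viol_lo, -g, 0.0) + np.where(viol_hi, g, 0.0)
            W[int(np.argmax(score))] = 0
            continue

        # line search to the nearest blocking bound
        alpha = 1.0
        block = -1
        side = 0
        for i in np.flatnonzero(free):
            if p[i] > atol and np.isfinite(ub[i]):
                a = (ub[i] - x[i]) / p[i]
                if a < alpha - 1e-14:
                    alpha, block, side = a, i, +1
            elif p[i] < -atol and np.isfinite(lb[i]):
                a = (lb[i] - x[i]) / p[i]
                if a < alpha - 1e-14:
                    alpha, block, side = a, i, -1
        alpha = max(alpha, 0.0)
        x = x + alpha * p
        if block >= 0:
            x[block] = ub[block] if side > 0 else lb[block]
            W[block] = side
        x = np.clip(x, lb, ub)
    return x, lam, False


def _bound_multiplier_lam(q, A, x, W=None):
    """Least-squares multipliers for the balance rows given the free block.

    Stationarity on free variables: q_i x_i - (A^T lam)_i = 0; solve for
    lam in least squares over the free columns (all columns if W None).
    """
    if W is None:
        cols = np.ones(len(q), dtype=bool)
    else:
        cols = W == 0
    if not cols.any():
        cols = np.ones(len(q), dtype=bool)
    g = q * x
    lam, *_ = np.linalg.lstsq(A[:, cols].T, g[cols], rcond=None)
    return lam


def _finish(problem, x, n_slack, A, b, lb, ub, q, lam=None):
    n = problem.n
    v = x[:n]
    obj = float(np.sum(problem.weights * v**2))
    balance = float(np.max(np.abs(problem.S @ v))) if problem.S.size else 0.0
    bviol = float(np.max(np.maximum(problem.lb - v, 0.0)
                         + np.maximum(v - problem.ub, 0.0)))
    if problem.couplings is not None and problem.coupling_rhs is not None \
            and problem.coupling_lo is None:
        balance = max(balance,
                      float(np.max(np.abs(problem.couplings @ v
                                          - problem.coupling_rhs))))
    kkt = np.nan
    mult = None
    if lam is not None:
        g = q * x - A.T @ lam
        at_lo = x - lb <= 1e-8 * (1.0 + np.abs(x))
        at_hi = ub - x <= 1e-8 * (1.0 + np.abs(x))
        interior = ~(at_lo | at_hi)
        kkt = float(np.max(np.abs(g[interior]))) if interior.any() else 0.0
        mult = {"balance": lam[:problem.S.shape[0]],
                "coupling": lam[problem.S.shape[0]:],
                "bounds": g[:n]}
    return FluxSolution(
        v=v, objective=obj, status="optimal",
        reaction_ids=list(problem.reaction_ids),
        balance_residual=balance, bound_violation=bviol,
        kkt_residual=kkt, multipliers=mult,
    )


def _minimize_flux_l1(problem: FluxProblem) -> FluxSolution:
    """Weighted L1 flux minimization via the split v = v+ - v-."""
    q, A, b, lb, ub, n_slack = _augmented(problem)
    n = len(q)
    w = np.concatenate([problem.weights, np.zeros(n_slack)])
    # variables [v, v+, v-]; v - v+ + v- = 0, v+/- >= 0
    A_eq = np.block([[A, np.zeros((A.shape[0], 2 * n))],
                     [np.eye(n), -np.eye(n), np.eye(n)]])
    b_eq = np.concatenate([b, np.zeros(n)])
    c = np.concatenate([np.zeros(n), w, w])
    bounds = list(zip(lb, ub)) + [(0, None)] * (2 * n)
    res = linprog(c=c, A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs")
    if res.status == 2:
        return FluxSolution(v=None, objective=None, status="infeasible",
                            reaction_ids=list(problem.reaction_ids))
    if res.status != 0:
        return FluxSolution(v=None, objective=None, status="numerical-failure",
                            reaction_ids=list(problem.reaction_ids))
    v = res.x[:problem.n]
    return FluxSolution(
        v=v, objective=float(np.sum(problem.weights * np.abs(v))),
        status="optimal", reaction_ids=list(problem.reaction_ids),
        balance_residual=float(np.max(np.abs(problem.S @ v))),
        bound_violation=float(np.max(np.maximum(problem.lb - v, 0.0)
                                     + np.maximum(v - problem.ub, 0.0))),
    )


# ----------------------------------------------------------------------
# brute-force oracle
# ----------------------------------------------------------------------

def solve_oracle_small(problem: FluxProblem, max_n: int = 12) -> FluxSolution:
    """Exact minimizer by exhaustive active-set enumeration (n <= 12).

    Every assignment of each variable to {free, at lower bound, at upper
    bound} is tried; the equality-constrained subproblem is solved in
    closed form through its KKT system, feasibility is checked, and the
    best feasible candidate wins. Independent of the iterative path
    taken by :func:`minimize_flux`.
    """
    problem.validate()
    q, A, b, lb, ub, n_slack = _augmented(problem)
    n = len(q)
    if n > max_n:
        raise ValueError(f"oracle refuses n={n} > {max_n} variables")

    states = []
    for i in range(n):
        s = [0]
        if np.isfinite(lb[i]):
            s.append(-1)
        if np.isfinite(ub[i]) and ub[i] > lb[i]:
            s.append(+1)
        states.append(s)

    best_x, best_obj = None, np.inf
    w_full = np.concatenate([problem.weights, np.zeros(n_slack)])
    for assign in product(*states):
        assign = np.array(assign)
        fixed = assign != 0
        xw = np.where(assign == -1, lb, np.where(assign == +1, ub, 0.0))
        free = ~fixed
        x = xw.copy()
        if free.any():
            r = b - A[:, fixed] @ xw[fixed]
            y, _, consistent = _solve_eqp(q[free], A[:, free], r)
            if not consistent:
                continue
            x[free] = y
        else:
            if np.linalg.norm(A @ x - b) > 1e-7 * (1.0 + np.linalg.norm(b)):
                continue
        if np.any(x < lb - 1e-8) or np.any(x > ub + 1e-8):
            continue
        obj = float(np.sum(w_full * x**2))
        if obj < best_obj - 1e-12:
            best_obj, best_x = obj, x

    if best_x is None:
        return FluxSolution(v=None, objective=None, status="infeasible",
                            reaction_ids=list(problem.reaction_ids))
    v = best_x[:problem.n]
    return FluxSolution(
        v=v, objective=float(np.sum(problem.weights * v**2)), status="optimal",
        reaction_ids=list(problem.reaction_ids),
        balance_residual=float(np.max(np.abs(problem.S @ v))),
        bound_violation=float(np.max(np.maximum(problem.lb - v, 0.0)
                                     + np.maximum(v - problem.ub, 0.0))),
    )


# ----------------------------------------------------------------------
# KKT verification
# ----------------------------------------------------------------------

@dataclass
class KKTReport:
    stationarity: float
    primal_balance: float
    primal_bounds: float
    complementarity: float
    sign_violation: float
    tol: float

    @property
    def ok(self) -> bool:
        return max(self.stationarity, self.primal_balance, self.primal_bounds,
                   self.complementarity, self.sign_violation) <= self.tol


def check_kkt(problem: FluxProblem, solution: FluxSolution,
              tol: float = _OPT_TOL) -> KKTReport:
    """Verify first-order optimality of a solution, from scratch.

    Multipliers for the balance and coupling rows are recomputed by
    least squares from the stationarity condition restricted to strictly
    interior variables; bound multipliers are then read off the residual
    gradient and checked for sign and complementary slackness.
    """
    if not solution.ok:
        raise ValueError("check_kkt requires an optimal solution")
    q, A, b, lb, ub, _ = _augmented(problem)
    n = len(q)
    x = np.zeros(n)
    x[:problem.n] = solution.v
    if n > problem.n:  # recover interval-coupling slack values
        x[problem.n:] = problem.couplings @ solution.v

    scale = 1.0 + float(np.max(np.abs(x)))
    at_lo = x - lb <= tol * scale
    at_hi = ub - x <= tol * scale
    interior = ~(at_lo | at_hi)

    g0 = q * x
    if interior.any():
        lam, *_ = np.linalg.lstsq(A[:, interior].T, g0[interior], rcond=None)
    else:
        lam, *_ = np.linalg.lstsq(A.T, g0, rcond=None)
    mu = g0 - A.T @ lam  # = mu_lb - mu_ub

    stationarity = float(np.max(np.abs(mu[interior]))) if interior.any() else 0.0
    primal_balance = float(np.max(np.abs(A @ x - b)))
    primal_bounds = float(np.max(np.maximum(lb - x, 0.0) + np.maximum(x - ub, 0.0)))
    # complementary slackness: mu must vanish off the active set
    comp = stationarity
    # sign: mu >= 0 where only the lower bound is active, <= 0 where upper
    sign_viol = 0.0
    only_lo = at_lo & ~at_hi
    only_hi = at_hi & ~at_lo
    if only_lo.any():
        sign_viol = max(sign_viol, float(np.max(np.maximum(-mu[only_lo], 0.0))))
    if only_hi.any():
        sign_viol = max(sign_viol, float(np.max(np.maximum(mu[only_hi], 0.0))))
    return KKTReport(
        stationarity=stationarity, primal_balance=primal_balance,
        primal_bounds=primal_bounds, complementarity=comp,
        sign_violation=sign_viol, tol=tol,
    )


# ----------------------------------------------------------------------
# infeasibility diagnosis
# ----------------------------------------------------------------------

@dataclass
class RelaxationReport:
    entries: list  # (constraint label, required slack) sorted by |slack| desc

    @property
    def empty(self) -> bool:
        return not self.entries


def diagnose_infeasibility(problem: FluxProblem, tol: float = 1e-7
                           ) -> RelaxationReport:
    """Rank the fixed exchange / coupling constraints blocking feasibility.

    Solves an elastic LP: every fixed flux (lb == ub) and every coupling
    row receives a signed slack, total |slack| is minimized subject to
    the hard mass balance, irreversibility and capacity bounds. The
    entries say which constraints must move, and by how much, for the
    problem to become feasible. Empty report: the problem is feasible
    as given.
    """
    problem.validate()
    q, A, b, lb, ub, n_slack = _augmented(problem)
    n = len(q)
    fixed = np.flatnonzero(lb == ub)
    labels = [problem.reaction_ids[i] if i < problem.n else f"coupling[{i - problem.n}]"
              for i in fixed]
    if problem.couplings is not None and problem.coupling_lo is None:
        # equality couplings live in A; make their rows elastic as well
        k = problem.couplings.shape[0]
        m0 = problem.S.shape[0]
        elastic_rows = list(range(m0, m0 + k))
    else:
        elastic_rows = []

    ne = len(fixed) + len(elastic_rows)
    # variables: x (n), e+ (ne), e- (ne)
    lb_x, ub_x = lb.copy(), ub.copy()
    lb_x[fixed] = -np.inf
    ub_x[fixed] = np.inf
    # but keep irreversibility where it came from a sign restriction:
    # a fixed value is relaxed fully; direction information stays in the report.
    A_el = np.hstack([A, np.zeros((A.shape[0], 2 * ne))])
    rows = []
    rhs = []
    for k_i, i in enumerate(fixed):
        row = np.zeros(n + 2 * ne)
        row[i] = 1.0
        row[n + k_i] = 1.0
        row[n + ne + k_i] = -1.0
        rows.append(row)
        rhs.append(lb[i])
    for k_i, ri in enumerate(elastic_rows, start=len(fixed)):
        A_el[ri, n + k_i] = 1.0
        A_el[ri, n + ne + k_i] = -1.0
        labels.append(f"coupling[{ri - problem.S.shape[0]}]")
    A_eq = np.vstack([A_el] + rows) if rows else A_el
    b_eq = np.concatenate([b, np.array(rhs)]) if rhs else b
    c = np.concatenate([np.zeros(n), np.ones(2 * ne)])
    bounds = list(zip(lb_x, ub_x)) + [(0, None)] * (2 * ne)
    res = linprog(c=c, A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs")
    if res.status != 0:
        raise ValueError(
            "elastic relaxation is itself infeasible: the hard constraints "
            "(mass balance + directionality + capacities) are inconsistent")
    e_plus = res.x[n:n + ne]
    e_minus = res.x[n + ne:]
    slack = e_minus - e_plus  # constraint value must move by this much
    entries = [(lab, float(s)) for lab, s in zip(labels, slack) if abs(s) > tol]
    entries.sort(key=lambda t: -abs(t[1]))
    return RelaxationReport(entries=entries)


def write_solution_tsv(problem: FluxProblem, solution: FluxSolution, path,
                       tol: float = 1e-9) -> None:
    """Write `reaction_id  flux  lb  ub  at_bound` sorted by reaction id."""
    rows = []
    for i, rid in enumerate(problem.reaction_ids):
        v = float(solution.v[i])
        at = int(abs(v - problem.lb[i]) <= tol * (1 + abs(v))
                 or abs(v - problem.ub[i]) <= tol * (1 + abs(v)))
        rows.append((rid, v, problem.lb[i], problem.ub[i], at))
    rows.sort()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("reaction_id\tflux\tlb\tub\tat_bound\n")
        for rid, v, lo, hi, at in rows:
            fh.write(f"{rid}\t{v:.12g}\t{lo:.12g}\t{hi:.12g}\t{at}\n")
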