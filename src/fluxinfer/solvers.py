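"""Thin adapters around the numerical back ends.

All linear programs go through HiGHS (``scipy.optimize.linprog``).  The two
quadratic problems the package needs — the l2-norm minimization at a fixed
LP optimum, and projection of a weight vector onto the flux cone — both have
an identity Hessian, i.e. they are Euclidean projections onto a polyhedron:

    min ||v - target||^2   s.t.   A_eq v = b_eq,  A_ub v <= b_ub,  lb <= v <= ub

Two independent QP back ends are provided: OSQP (operator splitting with
polishing) and scipy's trust-constr (interior point style).  Having two
genuinely different algorithms lets the test suite verify solution
uniqueness by solver swap.  Infinite bounds are passed through natively.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, sparse

logger = logging.getLogger(__name__)

QP_BACKENDS = ("osqp", "scipy")


class SolverError(RuntimeError):
    pass


class InfeasibleError(SolverError):
    pass


class UnboundedError(SolverError):
    pass


@dataclass
class LPResult:
    x: np.ndarray
    objective: float
    status: str


@dataclass
class QPResult:
    x: np.ndarray
    objective: float  # ||x - target||^2
    status: str
    backend: str


def solve_lp(
    c: np.ndarray,
    A_eq: Optional[sparse.spmatrix],
    b_eq: Optional[np.ndarray],
    lb: np.ndarray,
    ub: np.ndarray,
    A_ub: Optional[np.ndarray] = None,
    b_ub: Optional[np.ndarray] = None,
    maximize: bool = True,
    tol: float = 1e-9,
) -> LPResult:
    """Solve an LP with HiGHS.  Raises on infeasible/unbounded models."""
    c = np.asarray(c, dtype=float)
    if A_eq is not None and b_eq is None:
        b_eq = np.zeros(A_eq.shape[0])
    sign = -1.0 if maximize else 1.0
    res = optimize.linprog(
        sign * c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=np.column_stack([lb, ub]),
        method="highs",
        options={"primal_feasibility_tolerance": tol,
                 "dual_feasibility_tolerance": tol},
    )
    if res.status == 2:
        raise InfeasibleError(f"LP infeasible: {res.message}")
    if res.status == 3:
        raise UnboundedError(f"LP unbounded: {res.message}")
    if res.status != 0:
        raise SolverError(f"LP failed (status {res.status}): {res.message}")
    return LPResult(x=res.x, objective=float(c @ res.x), status="optimal")


def project_polyhedron(
    target: np.ndarray,
    A_eq: Optional[sparse.spmatrix],
    b_eq: Optional[np.ndarray],
    lb: np.ndarray,
    ub: np.ndarray,
    A_ub: Optional[np.ndarray] = None,
    b_ub: Optional[np.ndarray] = None,
    backend: str = "osqp",
    tol: float = 1e-8,
    x0: Optional[np.ndarray] = None,
) -> QPResult:
    """Euclidean projection of ``target`` onto a polyhedron.

    Solves min ||v - target||^2 subject to the given linear constraints.
    The solution is unique (strictly convex objective over a convex set).
    """
    target = np.asarray(target, dtype=float)
    n = target.size
    if backend == "osqp":
        return _project_osqp(target, A_eq, b_eq, lb, ub, A_ub, b_ub, tol)
    if backend == "scipy":
        return _project_scipy(target, A_eq, b_eq, lb, ub, A_ub, b_ub, tol, x0)
    raise ValueError(f"unknown QP backend {backend!r}; choose from {QP_BACKENDS}")


def _stack_rows(n, A_eq, b_eq, lb, ub, A_ub, b_ub):
    """Assemble OSQP-style row constraints l <= A x <= u."""
    blocks = []
    lo = []
    hi = []
    if A_eq is not None and A_eq.shape[0]:
        blocks.append(sparse.csc_matrix(A_eq))
        beq = np.zeros(A_eq.shape[0]) if b_eq is None else np.asarray(b_eq, float)
        lo.append(beq)
        hi.append(beq)
    blocks.append(sparse.identity(n, format="csc"))
    lo.append(np.asarray(lb, float))
    hi.append(np.asarray(ub, float))
    if A_ub is not None and len(A_ub):
        blocks.append(sparse.csc_matrix(np.atleast_2d(A_ub)))
        lo.append(np.full(len(b_ub), -np.inf))
        hi.append(np.asarray(b_ub, float))
    A = sparse.vstack(blocks, format="csc")
    return A, np.concatenate(lo), np.concatenate(hi)


def _polish_projection(target, x, A_eq, b_eq, lb, ub, A_ub, b_ub, tol=1e-7):
    """Refine an approximate projection by an exact active-set KKT solve.

    Constraints active at ``x`` (bounds and inequality rows within ``tol``)
    are treated as equalities; the equality-constrained projection has the
    closed form v = target + B' (B B')^+ (d - B target).  The refined point
    is accepted only if it stays feasible and does not worsen the objective.
    """
    n = target.size
    rows = []
    rhs = []
    if A_eq is not None and A_eq.shape[0]:
        dense = np.asarray(sparse.csr_matrix(A_eq).todense())
        rows.append(dense)
        rhs.append(np.zeros(dense.shape[0]) if b_eq is None else np.asarray(b_eq, float))
    eye = np.eye(n)
    for j in range(n):
        if np.isfinite(lb[j]) and x[j] - lb[j] < tol:
            rows.append(eye[j][None, :])
            rhs.append(np.array([lb[j]]))
        elif np.isfinite(ub[j]) and ub[j] - x[j] < tol:
            rows.append(eye[j][None, :])
            rhs.append(np.array([ub[j]]))
    if A_ub is not None and len(A_ub):
        A_ub = np.atleast_2d(A_ub)
        slack = np.asarray(b_ub, float) - A_ub @ x
        for i in range(A_ub.shape[0]):
            if slack[i] < tol:
                rows.append(A_ub[i][None, :])
                rhs.append(np.array([b_ub[i]]))
    if not rows:
        return x
    B = np.vstack(rows)
    d = np.concatenate(rhs)
    try:
        lam = np.linalg.lstsq(B @ B.T, d - B @ target, rcond=None)[0]
    except np.linalg.LinAlgError:
        return x
    v = target + B.T @ lam
    feas = 1e-9
    if np.any(v < lb - feas) or np.any(v > ub + feas):
        return x
    if A_ub is not None and len(A_ub) and np.any(A_ub @ v > np.asarray(b_ub) + feas):
        return x
    if np.sum((v - target) ** 2) <= np.sum((x - target) ** 2) + feas:
        return v
    return x


def _project_osqp(target, A_eq, b_eq, lb, ub, A_ub, b_ub, tol):
    import osqp

    n = target.size
    A, lo, hi = _stack_rows(n, A_eq, b_eq, lb, ub, A_ub, b_ub)
    P = sparse.identity(n, format="csc") * 2.0
    q = -2.0 * target
    prob = osqp.OSQP()
    prob.setup(
        P, q, A, lo, hi,
        eps_abs=tol * 1e-2,
        eps_rel=tol * 1e-2,
        max_iter=400000,
        polishing=True,
        verbose=False,
    )
    res = prob.solve(raise_error=False)
    status = res.info.status
    if "infeasible" in status:
        raise InfeasibleError(f"QP infeasible (osqp: {status})")
    if "solved" not in status:
        raise SolverError(f"QP failed (osqp: {status})")
    x = _polish_projection(target, np.asarray(res.x, dtype=float),
                           A_eq=A_eq, b_eq=b_eq, lb=lb, ub=ub,
                           A_ub=A_ub, b_ub=b_ub)
    return QPResult(
        x=x,
        objective=float(np.sum((x - target) ** 2)),
        status="optimal",
        backend="osqp",
    )


def _project_scipy(target, A_eq, b_eq, lb, ub, A_ub, b_ub, tol, x0):
    n = target.size
    constraints = []
    if A_eq is not None and A_eq.shape[0]:
        beq = np.zeros(A_eq.shape[0]) if b_eq is None else np.asarray(b_eq, float)
        constraints.append(optimize.LinearConstraint(A_eq, beq, beq))
    if A_ub is not None and len(A_ub):
        constraints.append(
            optimize.LinearConstraint(
                np.atleast_2d(A_ub), -np.inf, np.asarray(b_ub, float)
            )
        )
    if x0 is None:
        x0 = np.clip(target, lb, ub)
    # start from a feasible-ish interior point: project roughly with an LP
    fun = lambda v: float(np.sum((v - target) ** 2))
    jac = lambda v: 2.0 * (v - target)
    hess = lambda v: 2.0 * np.eye(n)
    res = optimize.minimize(
        fun,
        x0,
        jac=jac,
        hess=hess,
        bounds=optimize.Bounds(np.asarray(lb, float), np.asarray(ub, float)),
        constraints=constraints,
        method="trust-constr",
        options={"gtol": tol * 1e-4, "xtol": tol * 1e-6, "maxiter": 5000,
                 "sparse_jacobian": False},
    )
    if res.status not in (1, 2):  # 1: gtol, 2: xtol
        if "infeasible" in (res.message or "").lower():
            raise InfeasibleError(f"QP infeasible (trust-constr): {res.message}")
        logger.warning("trust-constr finished with status %s: %s", res.status, res.message)
    x = _polish_projection(target, np.asarray(res.x, dtype=float),
                           A_eq=A_eq, b_eq=b_eq, lb=lb, ub=ub,
                           A_ub=A_ub, b_ub=b_ub)
    return QPResult(
        x=x,
        objective=float(np.sum((x - target) ** 2)),
        status="optimal",
        backend="scipy",
    )


def maximize_linear_with_norm_cap(
    w: np.ndarray,
    A_eq: Optional[sparse.spmatrix],
    lb: np.ndarray,
    ub: np.ndarray,
    A_ub: Optional[np.ndarray] = None,
    b_ub: Optional[np.ndarray] = None,
    norm_matrix: Optional[np.ndarray] = None,
    maximize: bool = True,
    tol: float = 1e-8,
    x0: Optional[np.ndarray] = None,
) -> QPResult:
    """Optimize a linear objective over a polyhedron capped by ||M x|| <= 1.

    Used by the correlation-range computation.  ``norm_matrix`` M defaults to
    the identity.  Convex in both directions (linear objective, convex
    feasible set); solved with trust-constr.
    """
    w = np.asarray(w, dtype=float)
    n = w.size
    M = np.eye(n) if norm_matrix is None else np.asarray(norm_matrix, float)
    MtM = M.T @ M
    sign = -1.0 if maximize else 1.0
    constraints = []
    if A_eq is not None and A_eq.shape[0]:
        z = np.zeros(A_eq.shape[0])
        constraints.append(optimize.LinearConstraint(A_eq, z, z))
    if A_ub is not None and len(A_ub):
        constraints.append(
            optimize.LinearConstraint(np.atleast_2d(A_ub), -np.inf, np.asarray(b_ub, float))
        )
    constraints.append(
        optimize.NonlinearConstraint(
            lambda x: float(x @ MtM @ x),
            -np.inf,
            1.0,
            jac=lambda x: 2.0 * (MtM @ x),
            hess=lambda x, v: 2.0 * v[0] * MtM,
        )
    )
    if x0 is None:
        x0 = np.zeros(n)
    res = optimize.minimize(
        lambda x: sign * float(w @ x),
        x0,
        jac=lambda x: sign * w,
        hess=lambda x: np.zeros((n, n)),
        bounds=optimize.Bounds(np.asarray(lb, float), np.asarray(ub, float)),
        constraints=constraints,
        method="trust-constr",
        options={"gtol": tol * 1e-2, "xtol": tol * 1e-4, "maxiter": 5000,
                 "sparse_jacobian": False},
    )
    if res.status == 0:
        raise SolverError(f"norm-capped program did not converge: {res.message}")
    x = np.asarray(res.x, dtype=float)
    return QPResult(
        x=x, objective=float(w @ x), status="optimal", backend="trust-constr"
    )
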