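"""Flux-inference methods.

Six solvers share the steady-state constraint S v = 0 and differ in bounds
and objective:

* ``solve_fba`` — maximize f'v over the given bounds (LP; possibly
  degenerate optimum).
* ``solve_eflux`` — FBA over expression-capped bounds (LP; possibly
  degenerate).
* ``solve_eflux2`` — E-Flux followed by minimization of the squared
  Euclidean norm at the retained optimum; the strictly convex second step
  makes the solution unique.
* ``solve_spot`` — maximize the uncentered correlation between flux and
  reaction expression, reformulated as a linear objective over the
  decomposed nonnegative flux cone capped by a unit Euclidean norm.  Solved
  by Euclidean projection of the weight vector onto the cone: for a closed
  convex cone K, argmax {g.v : v in K, ||v|| <= 1} = P_K(g)/||P_K(g)||.
* ``solve_fba_min_l2`` — FBA on the model's own (measured-uptake) bounds
  followed by l2 minimization; unique.
* ``solve_pfba`` — FBA followed by l1 (total flux) minimization via the
  standard split-variable LP; not necessarily unique.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Union

import numpy as np
import pandas as pd
from scipy import sparse

from .expression import Decomposition, EFluxBounds
from .model import INF, MetabolicModel
from .solvers import (
    LPResult,
    QPResult,
    SolverError,
    UnboundedError,
    maximize_linear_with_norm_cap,
    project_polyhedron,
    solve_lp,
)
from .template import TemplateModel

logger = logging.getLogger(__name__)

DEFAULT_TOL_LP = 1e-9
DEFAULT_TOL_QP = 1e-8
DEFAULT_EPS_OBJ = 1e-6


@dataclass
class FluxDistribution:
    """A per-reaction flux vector (arbitrary units) plus solve metadata."""

    fluxes: pd.Series
    method: str
    objective_value: float
    status: str
    solver: str
    tolerances: Dict[str, float] = field(default_factory=dict)
    bounds_used: Optional[pd.DataFrame] = None
    extras: Dict[str, object] = field(default_factory=dict)

    def as_array(self, reaction_ids: Optional[List[str]] = None) -> np.ndarray:
        if reaction_ids is None:
            return self.fluxes.to_numpy()
        return self.fluxes.reindex(reaction_ids).to_numpy()

    def write_table(self, path) -> None:
        frame = pd.DataFrame({"reaction_id": self.fluxes.index, "flux": self.fluxes.values})
        if self.bounds_used is not None:
            frame["lower_bound_used"] = self.bounds_used["lower"].values
            frame["upper_bound_used"] = self.bounds_used["upper"].values
        frame.to_csv(path, sep="\t", index=False)

    def metadata(self) -> Dict[str, object]:
        return {
            "method": self.method,
            "objective_value": self.objective_value,
            "status": self.status,
            "solver": self.solver,
            "tolerances": self.tolerances,
            **{k: v for k, v in self.extras.items() if _jsonable(v)},
        }

    def write_metadata(self, path) -> None:
        Path(path).write_text(json.dumps(self.metadata(), indent=2, default=str))


def _jsonable(v) -> bool:
    return isinstance(v, (int, float, str, bool, list, dict, type(None)))


def _objective_vector(model: MetabolicModel, objective) -> np.ndarray:
    if objective is None:
        f = np.asarray(model.objective, dtype=float)
        if not np.any(f):
            raise ValueError(
                "model has no default objective; pass an objective reaction id"
            )
        return f
    f = np.zeros(model.n_reactions)
    f[model.reaction_index(objective)] = 1.0
    return f


def _mass_balance(model: MetabolicModel, v: np.ndarray) -> float:
    r = model.stoichiometry @ v
    return float(np.max(np.abs(r))) if r.size else 0.0


def _bounds_frame(model, lb, ub) -> pd.DataFrame:
    return pd.DataFrame({"lower": lb, "upper": ub}, index=model.reaction_ids)


def solve_fba(
    model: MetabolicModel,
    objective: Optional[str] = None,
    tol: float = DEFAULT_TOL_LP,
) -> FluxDistribution:
    """Standard FBA: maximize f'v subject to S v = 0 and the model bounds.

    The optimum is in general a face, not a point; the returned vertex is
    flagged ``optimal_possibly_nonunique``.
    """
    f = _objective_vector(model, objective)
    res = solve_lp(
        f, model.stoichiometry, None, model.lower_bounds, model.upper_bounds, tol=tol
    )
    fluxes = pd.Series(res.x, index=model.reaction_ids)
    return FluxDistribution(
        fluxes=fluxes,
        method="fba",
        objective_value=res.objective,
        status="optimal_possibly_nonunique",
        solver="highs",
        tolerances={"feasibility": tol},
        bounds_used=_bounds_frame(model, model.lower_bounds, model.upper_bounds),
        extras={"mass_balance_inf_norm": _mass_balance(model, res.x)},
    )


def solve_eflux(
    template: TemplateModel,
    bounds: EFluxBounds,
    objective: Optional[str] = None,
    tol: float = DEFAULT_TOL_LP,
) -> FluxDistribution:
    """E-Flux: FBA over expression-capped bounds (LP, possibly degenerate)."""
    f = _objective_vector(template, objective)
    res = solve_lp(f, template.stoichiometry, None, bounds.lower, bounds.upper, tol=tol)
    fluxes = pd.Series(res.x, index=template.reaction_ids)
    return FluxDistribution(
        fluxes=fluxes,
        method="eflux",
        objective_value=res.objective,
        status="optimal_possibly_nonunique",
        solver="highs",
        tolerances={"feasibility": tol},
        bounds_used=_bounds_frame(template, bounds.lower, bounds.upper),
        extras={"mass_balance_inf_norm": _mass_balance(template, res.x)},
    )


def _min_l2_at_optimum(
    model: MetabolicModel,
    lb: np.ndarray,
    ub: np.ndarray,
    f: np.ndarray,
    z_star: float,
    eps_obj: float,
    tol: float,
    backend: str,
) -> QPResult:
    # retain optimality through the inequality f'v >= z*(1 - eps); exact
    # equality against an LP-reported optimum is numerically brittle
    z_floor = z_star - eps_obj * abs(z_star)
    return project_polyhedron(
        target=np.zeros(model.n_reactions),
        A_eq=model.stoichiometry,
        b_eq=None,
        lb=lb,
        ub=ub,
        A_ub=-f[None, :],
        b_ub=np.array([-z_floor]),
        backend=backend,
        tol=tol,
    )


def solve_eflux2(
    template: TemplateModel,
    bounds: EFluxBounds,
    objective: Optional[str] = None,
    tol: float = DEFAULT_TOL_QP,
    eps_obj: float = DEFAULT_EPS_OBJ,
    backend: str = "osqp",
) -> FluxDistribution:
    """E-Flux2: E-Flux, then the unique l2-norm-minimal optimal flux."""
    step1 = solve_eflux(template, bounds, objective)
    f = _objective_vector(template, objective)
    z_star = step1.objective_value
    try:
        qp = _min_l2_at_optimum(
            template, bounds.lower, bounds.upper, f, z_star, eps_obj, tol, backend
        )
    except SolverError as exc:
        raise SolverError(
            f"E-Flux2 norm minimization failed after step-1 status "
            f"{step1.status!r} (z*={z_star}): {exc}"
        ) from exc
    fluxes = pd.Series(qp.x, index=template.reaction_ids)
    return FluxDistribution(
        fluxes=fluxes,
        method="eflux2",
        objective_value=z_star,
        status="optimal",
        solver=f"highs+{qp.backend}",
        tolerances={"feasibility": tol, "objective_retention": eps_obj},
        bounds_used=_bounds_frame(template, bounds.lower, bounds.upper),
        extras={
            "mass_balance_inf_norm": _mass_balance(template, qp.x),
            "l2_norm": float(np.linalg.norm(qp.x)),
            "objective_retained": float(f @ qp.x),
        },
    )


def solve_fba_min_l2(
    model: MetabolicModel,
    objective: Optional[str] = None,
    tol: float = DEFAULT_TOL_QP,
    eps_obj: float = DEFAULT_EPS_OBJ,
    backend: str = "osqp",
) -> FluxDistribution:
    """FBA on the model's own bounds followed by l2 minimization (unique)."""
    f = _objective_vector(model, objective)
    step1 = solve_lp(
        f, model.stoichiometry, None, model.lower_bounds, model.upper_bounds
    )
    qp = _min_l2_at_optimum(
        model, model.lower_bounds, model.upper_bounds, f, step1.objective,
        eps_obj, tol, backend,
    )
    fluxes = pd.Series(qp.x, index=model.reaction_ids)
    return FluxDistribution(
        fluxes=fluxes,
        method="fba_min_l2",
        objective_value=step1.objective,
        status="optimal",
        solver=f"highs+{qp.backend}",
        tolerances={"feasibility": tol, "objective_retention": eps_obj},
        bounds_used=_bounds_frame(model, model.lower_bounds, model.upper_bounds),
        extras={
            "mass_balance_inf_norm": _mass_balance(model, qp.x),
            "l2_norm": float(np.linalg.norm(qp.x)),
        },
    )


def solve_pfba(
    model: MetabolicModel,
    objective: Optional[str] = None,
    tol: float = DEFAULT_TOL_LP,
    eps_obj: float = DEFAULT_EPS_OBJ,
) -> FluxDistribution:
    """Parsimonious FBA: FBA then l1 (total flux) minimization.

    Split-variable LP: v = p - q with p, q >= 0 and minimize sum(p + q).
    The l1 norm is not strictly convex, so the result may be non-unique.
    """
    f = _objective_vector(model, objective)
    step1 = solve_lp(
        f, model.stoichiometry, None, model.lower_bounds, model.upper_bounds
    )
    z_floor = step1.objective - eps_obj * abs(step1.objective)
    n = model.n_reactions
    S = model.stoichiometry
    A_eq = sparse.hstack([S, -S], format="csc")
    lb2 = np.zeros(2 * n)
    ub2 = np.full(2 * n, INF)
    rows: List[np.ndarray] = []
    rhs: List[float] = []
    eye = np.eye(n)
    for j in range(n):
        if np.isfinite(model.upper_bounds[j]):
            rows.append(np.concatenate([eye[j], -eye[j]]))
            rhs.append(model.upper_bounds[j])
        if np.isfinite(model.lower_bounds[j]):
            rows.append(np.concatenate([-eye[j], eye[j]]))
            rhs.append(-model.lower_bounds[j])
    rows.append(np.concatenate([-f, f]))
    rhs.append(-z_floor)
    res = solve_lp(
        np.ones(2 * n),
        A_eq,
        None,
        lb2,
        ub2,
        A_ub=np.array(rows),
        b_ub=np.array(rhs),
        maximize=False,
        tol=tol,
    )
    v = res.x[:n] - res.x[n:]
    fluxes = pd.Series(v, index=model.reaction_ids)
    return FluxDistribution(
        fluxes=fluxes,
        method="pfba",
        objective_value=step1.objective,
        status="optimal_possibly_nonunique",
        solver="highs",
        tolerances={"feasibility": tol, "objective_retention": eps_obj},
        bounds_used=_bounds_frame(model, model.lower_bounds, model.upper_bounds),
        extras={
            "mass_balance_inf_norm": _mass_balance(model, v),
            "l1_norm": float(np.sum(np.abs(v))),
        },
    )


def solve_spot(
    template: TemplateModel,
    decomposition: Decomposition,
    tol: float = DEFAULT_TOL_QP,
    backend: str = "osqp",
    simultaneous_tol: float = 1e-6,
) -> FluxDistribution:
    """SPOT: maximize v.g over the decomposed flux cone with ||v|| <= 1.

    ``backend`` "osqp"/"scipy" solve the equivalent cone-projection QP
    min ||v - g||^2 over {S v = 0, v >= 0} and normalize; "socp" solves the
    norm-capped program directly (slower; kept as an independent route).
    The solution is unique whenever the projection is nonzero.
    """
    d = decomposition
    g = d.weights
    n_bar = g.size
    lb = np.zeros(n_bar)
    ub = d.upper.copy()
    if not np.any(g > 0):
        logger.warning("SPOT: all expression weights are zero; returning zero flux")
        v = np.zeros(template.n_reactions)
        return _spot_result(template, d, v, np.zeros(n_bar), tol, backend)
    if backend == "socp":
        res = maximize_linear_with_norm_cap(
            g, d.S_bar, lb, ub, tol=tol, maximize=True
        )
        v_bar = res.x
    else:
        proj = project_polyhedron(
            target=g, A_eq=d.S_bar, b_eq=None, lb=lb, ub=ub, backend=backend, tol=tol
        )
        norm = float(np.linalg.norm(proj.x))
        if norm <= 1e3 * tol:
            logger.warning(
                "SPOT: expression weights are orthogonal to the feasible cone; "
                "returning zero flux"
            )
            v_bar = np.zeros(n_bar)
        else:
            v_bar = proj.x / norm
    v = d.recombine(v_bar)
    return _spot_result(template, d, v, v_bar, tol, backend)


def _spot_result(template, d, v, v_bar, tol, backend) -> FluxDistribution:
    g = d.weights
    objective = float(v_bar @ g)
    # realized uncentered correlation between recombined flux and reaction
    # expression, over GPR-mapped reactions and over all reactions
    g_rxn = np.zeros(template.n_reactions)
    has_g = np.zeros(template.n_reactions, dtype=bool)
    for col in range(g.size):
        j = d.orig_index[col]
        if g[col] > 0:
            g_rxn[j] = g[col]
            has_g[j] = True
    corr_mapped = _uncentered(v[has_g], g_rxn[has_g])
    corr_all = _uncentered(v, g_rxn)
    # simultaneous forward/backward activity diagnostics
    fwd: Dict[int, float] = {}
    bwd: Dict[int, float] = {}
    for col, kind in enumerate(d.kind):
        if kind == "rev_f":
            fwd[d.orig_index[col]] = v_bar[col]
        elif kind == "rev_b":
            bwd[d.orig_index[col]] = v_bar[col]
    simultaneous = [
        template.reaction_ids[j]
        for j in fwd
        if min(fwd[j], bwd.get(j, 0.0)) > 1e-6
    ]
    fluxes = pd.Series(v, index=template.reaction_ids)
    return FluxDistribution(
        fluxes=fluxes,
        method="spot",
        objective_value=objective,
        status="optimal" if np.any(v_bar) else "zero",
        solver=backend,
        tolerances={"feasibility": tol},
        bounds_used=_bounds_frame(template, template.lower_bounds, template.upper_bounds),
        extras={
            "mass_balance_inf_norm": _mass_balance(template, v),
            "decomposed_norm": float(np.linalg.norm(v_bar)),
            "correlation_mapped_reactions": corr_mapped,
            "correlation_all_reactions": corr_all,
            "simultaneous_forward_backward": simultaneous,
        },
    )


def _uncentered(x: np.ndarray, y: np.ndarray) -> Optional[float]:
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0 or ny == 0:
        return None
    return float(x @ y / (nx * ny))
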