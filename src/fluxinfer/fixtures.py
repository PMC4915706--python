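"""Synthetic fixture networks with known ground truth, plus grid oracles.

Every optimization method in this package can be exercised on these small
networks without downloading any genome-scale model.  Each topology is built
so that the solution of at least one method is known in closed form or is
reachable by dense grid search over a low-dimensional feasible space:

* ``chain`` — linear pathway; every method's flux is fully determined.
* ``branch`` — two isozymatic routes; the l2-minimal optimum splits the
  flux evenly, and the E-Flux optimal face has one degree of freedom.
* ``cycle`` — chain plus a futile two-cycle; l1 minimization zeroes it.
* ``spot_ratio`` — one uptake (weight 5) feeding two drains (weights 8 and
  2); the correlation-maximal flux carries the drains at a 19:1 ratio
  (from the stationarity conditions on the unit sphere).
* ``composite`` — branched network with a reversible step, AND/OR GPRs,
  several exchange reactions with formulas, and a measured-flux set; used
  by the command-line pipeline and the acceptance script.

Measured-flux sets are the ground-truth solution pushed through the mapping
rules, times an arbitrary unit factor, with optional seeded Gaussian noise.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import linalg, sparse

from .boolexpr import evaluate, parse as parse_rule
from .expression import Decomposition, ExpressionProfile
from .model import INF, MetabolicModel
from .solvers import solve_lp
from .template import TemplateModel
from .validation import MeasuredFluxSet, MeasuredRecord

logger = logging.getLogger(__name__)

TOPOLOGIES = ("chain", "branch", "cycle", "spot_ratio", "composite")


class GenerationError(ValueError):
    pass


class DOFError(ValueError):
    """Feasible space has too many degrees of freedom for grid search."""


@dataclass
class ToySpec:
    topology: str = "chain"
    n_routes: int = 2
    expression: Optional[Dict[str, float]] = None
    seed: int = 0
    noise_sigma: float = 0.0
    measured_unit: float = 2.0  # measured fluxes live in their own unit


def _build(mets, rxns, model_id) -> MetabolicModel:
    met_ids = [m for m, _ in mets]
    mi = {m: i for i, m in enumerate(met_ids)}
    rows, cols, data = [], [], []
    lb, ub, obj, gprs, rids = [], [], [], [], []
    for j, (rid, stoich, lo, hi, o, gpr) in enumerate(rxns):
        rids.append(rid)
        lb.append(lo)
        ub.append(hi)
        obj.append(o)
        gprs.append(parse_rule(gpr) if gpr else None)
        for met, coef in stoich.items():
            rows.append(mi[met])
            cols.append(j)
            data.append(float(coef))
    S = sparse.csc_matrix((data, (rows, cols)), shape=(len(met_ids), len(rxns)))
    return MetabolicModel(
        metabolite_ids=met_ids,
        reaction_ids=rids,
        stoichiometry=S,
        lower_bounds=np.array(lb, float),
        upper_bounds=np.array(ub, float),
        objective=np.array(obj, float),
        gpr=gprs,
        metabolite_formulas=[f for _, f in mets],
        compartments=["c"] * len(met_ids),
        model_id=model_id,
    )


def make_toy_model(
    spec: ToySpec,
) -> Tuple[MetabolicModel, ExpressionProfile, MeasuredFluxSet]:
    """Build a fixture network with its expression profile and measured set."""
    if spec.topology not in TOPOLOGIES:
        raise GenerationError(f"unknown topology {spec.topology!r}")
    if spec.n_routes < 1:
        raise GenerationError("a network needs at least one route to its sink")
    builder = {
        "chain": _chain,
        "branch": _branch,
        "cycle": _cycle,
        "spot_ratio": _spot_ratio,
        "composite": _composite,
    }[spec.topology]
    model, expr, clean_records = builder(spec)
    expression = dict(expr)
    if spec.expression:
        expression.update(spec.expression)
    rng = np.random.default_rng(spec.seed)
    records = []
    for mid, mapping, value in clean_records:
        noisy = value * spec.measured_unit + (
            rng.normal(0.0, spec.noise_sigma) if spec.noise_sigma > 0 else 0.0
        )
        records.append(MeasuredRecord(mid, parse_rule(mapping), noisy))
    measured = MeasuredFluxSet(records=records, condition=f"{spec.topology}-seed{spec.seed}")
    profile = ExpressionProfile(values=expression, condition=f"{spec.topology}-seed{spec.seed}")
    return model, profile, measured


def _chain(spec):
    mets = [("A", "C6H12O6"), ("B", "C6H12O6"), ("C", "C6H12O6")]
    rxns = [
        ("EX_A", {"A": -1}, -10.0, 1000.0, 0.0, ""),
        ("R1", {"A": -1, "B": 1}, 0.0, 1000.0, 0.0, "g1"),
        ("R2", {"B": -1, "C": 1}, 0.0, 1000.0, 0.0, "g2a and g2b"),
        ("BIO", {"C": -1}, 0.0, 1000.0, 1.0, ""),
    ]
    expr = {"g1": 4.0, "g2a": 5.0, "g2b": 3.0}
    # DC+E-Flux2 ground truth: chain carries min(4, 3) = 3
    records = [
        ("upper_pathway", "R1 and R2", 3.0),
        ("growth", "BIO", 3.0),
    ]
    return _build(mets, rxns, "toy_chain"), expr, records


def _branch(spec):
    mets = [("A", "C6H12O6"), ("B", "C6H12O6")]
    rxns = [("EX_A", {"A": -1}, -10.0, 1000.0, 0.0, "gup")]
    route_genes = []
    for k in range(spec.n_routes):
        gene = f"gu{k + 1}"
        route_genes.append(gene)
        rxns.append((f"RU{k + 1}", {"A": -1, "B": 1}, 0.0, 1000.0, 0.0, gene))
    rxns.append(("BIO", {"B": -1}, 0.0, 1000.0, 1.0, ""))
    expr = {"gup": 4.0}
    expr.update({g: 5.0 for g in route_genes})
    # uptake capacity 4 splits evenly over symmetric routes under min-l2
    per_route = 4.0 / spec.n_routes
    records = [
        (f"route{k + 1}", f"RU{k + 1}", per_route * (1.5 if k == 0 else 0.5))
        for k in range(min(spec.n_routes, 2))
    ]
    records.append(("growth", "BIO", 4.0))
    return _build(mets, rxns, "toy_branch"), expr, records


def _cycle(spec):
    mets = [("A", "C6H12O6"), ("B", "C6H12O6"), ("C", "C6H12O6")]
    rxns = [
        ("EX_A", {"A": -1}, -10.0, 1000.0, 0.0, ""),
        ("R1", {"A": -1, "B": 1}, 0.0, 1000.0, 0.0, "g1"),
        ("R2", {"B": -1, "C": 1}, 0.0, 1000.0, 0.0, "g2"),
        ("R3", {"C": -1, "B": 1}, 0.0, 1000.0, 0.0, "g3"),
        ("BIO", {"C": -1}, 0.0, 1000.0, 1.0, ""),
    ]
    expr = {"g1": 4.0, "g2": 5.0, "g3": 1.0}
    records = [("pathway", "R1 and R2", 4.0), ("growth", "BIO", 4.0)]
    return _build(mets, rxns, "toy_cycle"), expr, records


def _spot_ratio(spec):
    mets = [("A", "C6H12O6")]
    rxns = [
        ("R1", {"A": 1}, 0.0, 1000.0, 0.0, "gin"),
        ("R2", {"A": -1}, 0.0, 1000.0, 0.0, "gout1"),
        ("R3", {"A": -1}, 0.0, 1000.0, 0.0, "gout2"),
    ]
    expr = {"gin": 5.0, "gout1": 8.0, "gout2": 2.0}
    # stationarity on the unit sphere gives v2:v3 = 19:1, v1 = v2 + v3
    records = [("in", "R1", 20.0), ("out1", "R2", 19.0), ("out2", "R3", 1.0)]
    return _build(mets, rxns, "toy_spot_ratio"), expr, records


def _composite(spec):
    mets = [
        ("Glc", "C6H12O6"),
        ("F", "C3H6O3"),
        ("B", "C3H6O3"),
        ("C", "C3H6O3"),
        ("D", "C3H6O3"),
        ("W", "H2O"),
        ("CO2x", "CO2"),
    ]
    rxns = [
        ("EX_glc", {"Glc": -1}, -10.0, 1000.0, 0.0, ""),
        ("EX_f", {"F": -1}, 0.0, 1000.0, 0.0, ""),
        ("EX_w", {"W": -1}, -1000.0, 1000.0, 0.0, ""),
        ("EX_co2", {"CO2x": -1}, 0.0, 1000.0, 0.0, ""),
        ("RT1", {"Glc": -1, "B": 2}, 0.0, 1000.0, 0.0, "gt1a and gt1b"),
        ("RF", {"F": -1, "B": 1}, 0.0, 1000.0, 0.0, "gf"),
        ("RU1", {"B": -1, "C": 1}, 0.0, 1000.0, 0.0, "gu1"),
        ("RU2", {"B": -1, "C": 1}, 0.0, 1000.0, 0.0, "gu2"),
        ("RREV", {"C": -1, "D": 1}, -1000.0, 1000.0, 0.0, "gr1 or gr2"),
        ("BIO", {"D": -1}, 0.0, 1000.0, 1.0, ""),
    ]
    expr = {
        "gt1a": 6.0, "gt1b": 10.0, "gf": 0.0,
        "gu1": 5.0, "gu2": 3.0, "gr1": 4.0, "gr2": 3.0,
    }
    # DC+E-Flux2 ground truth: RT1 3.5 -> B 7 -> RU1 4 / RU2 3 -> RREV 7 -> BIO 7
    records = [
        ("uptake", "EX_glc", -3.5),
        ("transport", "RT1", 3.5),
        ("branch", "RU1 or RU2", 7.0),
        ("route_a", "RU1", 4.0),
        ("lower_pathway", "RREV and BIO", 7.0),
        ("growth", "BIO", 7.0),
    ]
    return _build(mets, rxns, "toy_composite"), expr, records


# ---------------------------------------------------------------------------
# file emission


def write_fixture_files(spec: ToySpec, directory) -> Dict[str, Path]:
    """Write SBML model, expression CSV and measured-flux CSV for a spec."""
    import pandas as pd

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    model, profile, measured = make_toy_model(spec)
    paths = {
        "model": directory / f"{model.model_id}.xml",
        "expression": directory / "expression.csv",
        "measured": directory / "measured.csv",
    }
    write_sbml(model, paths["model"])
    header = f"# topology={spec.topology} seed={spec.seed} sigma={spec.noise_sigma}\n"
    with open(paths["expression"], "w") as fh:
        fh.write(header)
        fh.write("gene,abundance\n")
        for g, v in profile.values.items():
            fh.write(f"{g},{v}\n")
    with open(paths["measured"], "w") as fh:
        fh.write(header)
        fh.write("measured_id,mapping,value\n")
        for rec in measured.records:
            fh.write(f"{rec.measured_id},{rec.mapping.to_string()},{rec.value}\n")
    return paths


def write_sbml(model: MetabolicModel, path) -> None:
    """Serialize a fixture model to SBML L3+fbc via cobrapy."""
    import cobra
    from cobra.io import write_sbml_model

    cm = cobra.Model(model.model_id)
    mets = []
    for i, mid in enumerate(model.metabolite_ids):
        m = cobra.Metabolite(
            mid,
            formula=model.metabolite_formulas[i],
            compartment=model.compartments[i] or "c",
        )
        mets.append(m)
    cm.add_metabolites(mets)
    S = model.stoichiometry.tocsc()
    for j, rid in enumerate(model.reaction_ids):
        r = cobra.Reaction(rid)
        r.lower_bound = float(model.lower_bounds[j])
        r.upper_bound = float(model.upper_bounds[j])
        cm.add_reactions([r])
        coefs = {}
        for k in range(S.indptr[j], S.indptr[j + 1]):
            coefs[mets[S.indices[k]]] = S.data[k]
        r.add_metabolites(coefs)
        if model.gpr[j] is not None:
            r.gene_reaction_rule = model.gpr[j].to_string()
    for j, rid in enumerate(model.reaction_ids):
        if model.objective[j] != 0.0:
            cm.reactions.get_by_id(rid).objective_coefficient = model.objective[j]
    write_sbml_model(cm, str(path), f_replace={})


def permute_reactions(model: MetabolicModel, perm: Sequence[int]):
    """Reorder reaction columns (used by order-invariance property tests)."""
    perm = list(perm)
    kwargs = dict(
        metabolite_ids=list(model.metabolite_ids),
        reaction_ids=[model.reaction_ids[j] for j in perm],
        stoichiometry=model.stoichiometry.tocsc()[:, perm],
        lower_bounds=model.lower_bounds[perm],
        upper_bounds=model.upper_bounds[perm],
        objective=model.objective[perm],
        gpr=[model.gpr[j] for j in perm],
        metabolite_formulas=list(model.metabolite_formulas),
        compartments=list(model.compartments),
        model_id=model.model_id,
    )
    if isinstance(model, TemplateModel):
        return TemplateModel(
            **kwargs,
            template_kind=model.template_kind,
            carbon_sources_opened=list(model.carbon_sources_opened),
        )
    return MetabolicModel(**kwargs)


# ---------------------------------------------------------------------------
# brute-force oracles


def _face_parameterization(S, lb, ub, f, eps_obj=1e-9):
    """Particular point and null-space basis of an LP's optimal face."""
    res = solve_lp(f, S, None, lb, ub)
    A = np.vstack([np.asarray(S.todense()), f[None, :]])
    Z = linalg.null_space(A)
    return res.x, Z, res.objective


def _grid_optimize(x0, Z, lb, ub, objective, grid, refine, minimize):
    """Dense grid search with iterative shrinkage around the incumbent."""
    dof = Z.shape[1]
    if dof == 0:
        return x0, objective(x0)
    # bound each coordinate by LPs in y-space
    lo = np.empty(dof)
    hi = np.empty(dof)
    from scipy.optimize import linprog

    finite_lb = np.where(np.isfinite(lb), lb, -1e9)
    finite_ub = np.where(np.isfinite(ub), ub, 1e9)
    A_ub = np.vstack([Z, -Z])
    b_ub = np.concatenate([finite_ub - x0, x0 - finite_lb])
    for k in range(dof):
        c = np.zeros(dof)
        c[k] = 1.0
        lo[k] = linprog(c, A_ub=A_ub, b_ub=b_ub, bounds=[(None, None)] * dof).fun
        hi[k] = -linprog(-c, A_ub=A_ub, b_ub=b_ub, bounds=[(None, None)] * dof).fun
    center = (lo + hi) / 2.0
    radius = (hi - lo) / 2.0
    best_y, best_val = None, None
    sign = 1.0 if minimize else -1.0
    for _ in range(refine):
        axes = [np.linspace(center[k] - radius[k], center[k] + radius[k], grid)
                for k in range(dof)]
        for y in itertools.product(*axes):
            y = np.asarray(y)
            v = x0 + Z @ y
            if np.any(v < lb - 1e-7) or np.any(v > ub + 1e-7):
                continue
            val = objective(v)
            if val is None:
                continue
            if best_val is None or sign * val < sign * best_val:
                best_val, best_y = val, y
        if best_y is None:
            raise DOFError("no feasible grid point found on the face")
        center = best_y
        radius = radius * (2.5 / (grid - 1))  # keep the incumbent interior
    return x0 + Z @ best_y, best_val


def oracle_min_l2_on_face(model, lb, ub, objective_vector, grid=41, refine=10,
                          max_dof=3):
    """Grid oracle for the l2-minimal point of an LP optimal face."""
    x0, Z, z_star = _face_parameterization(model.stoichiometry, lb, ub,
                                           objective_vector)
    if Z.shape[1] > max_dof:
        raise DOFError(f"face has {Z.shape[1]} degrees of freedom (> {max_dof})")
    v, val = _grid_optimize(
        x0, Z, lb, ub, lambda v: float(v @ v), grid, refine, minimize=True
    )
    return v, val, z_star


def oracle_spot(decomposition: Decomposition, grid=121, refine=10, max_dof=3):
    """Grid oracle for the correlation-maximal direction of the flux cone.

    Searches directions v = Z y over the null space of the decomposed
    stoichiometry, keeps the nonnegative ones, and maximizes g.v/||v||.
    Returns the unit-norm decomposed vector and the objective value.
    """
    S = np.asarray(decomposition.S_bar.todense())
    Z = linalg.null_space(S) if S.size else np.eye(decomposition.weights.size)
    dof = Z.shape[1]
    if dof > max_dof:
        raise DOFError(f"flux cone has {dof} degrees of freedom (> {max_dof})")
    g = decomposition.weights
    fixed_zero = decomposition.upper == 0.0

    def objective(y):
        v = Z @ y
        if np.any(v < -1e-9) or np.any(np.abs(v[fixed_zero]) > 1e-9):
            return None
        nv = np.linalg.norm(v)
        if nv < 1e-12:
            return None
        return float(g @ v / nv)

    center = np.zeros(dof)
    radius = np.ones(dof)
    best_y, best_val = None, None
    for _ in range(refine):
        axes = [np.linspace(center[k] - radius[k], center[k] + radius[k], grid)
                for k in range(dof)]
        for y in itertools.product(*axes):
            y = np.asarray(y)
            val = objective(y)
            if val is None:
                continue
            if best_val is None or val > best_val:
                best_val, best_y = val, y
        if best_y is None:
            return np.zeros(g.size), 0.0
        norm = np.linalg.norm(Z @ best_y)
        best_y = best_y / norm
        center = best_y
        radius = radius * (2.5 / (grid - 1))
    v = Z @ best_y
    v = np.clip(v, 0.0, None)
    v = v / np.linalg.norm(v)
    return v, float(g @ v)


def oracle_correlation_range(model, lb, ub, objective_vector, measured,
                             grid=201, refine=10, max_dof=3):
    """Grid oracle for the correlation range over an LP optimal face."""
    x0, Z, _ = _face_parameterization(model.stoichiometry, lb, ub,
                                      objective_vector)
    if Z.shape[1] > max_dof:
        raise DOFError(f"face has {Z.shape[1]} degrees of freedom (> {max_dof})")
    v_m = measured.values()
    ids = model.reaction_ids

    def corr(v):
        values = {r: v[j] for j, r in enumerate(ids)}
        matched = np.array(
            [evaluate(rec.mapping, values, "strict") for rec in measured.records]
        )
        nm = np.linalg.norm(matched)
        if nm < 1e-12:
            return None
        return float(matched @ v_m / (nm * np.linalg.norm(v_m)))

    _, cmax = _grid_optimize(x0, Z, lb, ub, corr, grid, refine, minimize=False)
    _, cmin = _grid_optimize(x0, Z, lb, ub, corr, grid, refine, minimize=True)
    return cmin, cmax


def brute_force_lowdof(model, method, *, lb=None, ub=None,
                       objective_vector=None, decomposition=None,
                       measured=None, grid=None, max_dof=3):
    """Dispatch to the grid oracle for ``method`` in {eflux2, spot, corr_range}.

    Refuses when the feasible space has more than ``max_dof`` free
    dimensions after fixing the optimal objective value.
    """
    if method == "eflux2":
        return oracle_min_l2_on_face(
            model, lb, ub, objective_vector, grid=grid or 41, max_dof=max_dof
        )
    if method == "spot":
        return oracle_spot(decomposition, grid=grid or 121, max_dof=max_dof)
    if method == "corr_range":
        return oracle_correlation_range(
            model, lb, ub, objective_vector, measured, grid=grid or 201,
            max_dof=max_dof,
        )
    raise ValueError(f"unknown oracle method {method!r}")
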