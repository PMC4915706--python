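"""Comparison of predicted fluxes with 13C-measured fluxes.

Measured central-carbon fluxes rarely map one-to-one onto genome-scale model
reactions.  Each measured record therefore carries a mapping rule over model
reaction identifiers written in the same AND/OR grammar as GPRs: AND chains
consecutive reactions in series (the matched prediction is the minimum — the
rate-limiting step), OR joins parallel reactions (the matched prediction is
the sum).  Agreement is scored with the uncentered Pearson correlation
x.y/(||x|| ||y||), which is insensitive to the arbitrary unit of the
predictions.

For methods whose optimum is a face rather than a point (FBA, E-Flux), the
range of correlations attainable over the optimal face is computed by
homogenizing the face into a cone and optimizing the matched inner product
under a unit norm cap on the matched vector — the same device that makes
SPOT a convex program.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import sparse

from .boolexpr import BoolExpr, evaluate, linear_pieces, parse as parse_rule, piece_count
from .expression import EFluxBounds, ReactionExpression
from .methods import FluxDistribution
from .model import MetabolicModel
from .solvers import SolverError, maximize_linear_with_norm_cap, solve_lp
from .template import TemplateModel

logger = logging.getLogger(__name__)


class ValidationError(ValueError):
    pass


@dataclass
class MeasuredRecord:
    measured_id: str
    mapping: BoolExpr
    value: float


@dataclass
class MeasuredFluxSet:
    """Measured reaction rates with mapping rules onto model reactions."""

    records: List[MeasuredRecord]
    condition: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def values(self) -> np.ndarray:
        return np.array([r.value for r in self.records], dtype=float)

    def check_against_model(self, model: MetabolicModel) -> None:
        known = set(model.reaction_ids)
        for rec in self.records:
            missing = [x for x in rec.mapping.leaves() if x not in known]
            if missing:
                raise ValidationError(
                    f"measured record {rec.measured_id!r} references unknown "
                    f"model reactions: {missing}"
                )


def read_measured_table(path, condition: str = "") -> MeasuredFluxSet:
    """Read a CSV with columns measured_id, mapping, value."""
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    required = {"measured_id", "mapping", "value"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"{path}: expected columns {sorted(required)}, got {list(df.columns)}"
        )
    records = [
        MeasuredRecord(
            measured_id=str(row.measured_id),
            mapping=parse_rule(str(row.mapping)),
            value=float(row.value),
        )
        for row in df.itertuples()
    ]
    return MeasuredFluxSet(records=records, condition=condition or path.stem)


@dataclass
class ValidationResult:
    """Matched predicted/measured vectors and the correlation between them."""

    measured_ids: List[str]
    predicted: np.ndarray
    measured: np.ndarray
    mappings: List[str]
    correlation: Optional[float] = None
    correlation_range: Optional[Tuple[float, float]] = None
    method: str = ""
    condition: str = ""

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "measured_id": self.measured_ids,
                "measured_value": self.measured,
                "predicted_value": self.predicted,
                "mapping": self.mappings,
            }
        )

    def summary(self) -> Dict[str, object]:
        out = {
            "method": self.method,
            "condition": self.condition,
            "n_records": len(self.measured_ids),
            "correlation": self.correlation,
        }
        if self.correlation_range is not None:
            out["correlation_min"], out["correlation_max"] = self.correlation_range
        return out


def uncentered_pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """x.y / (||x|| ||y||), in [-1, 1].  Undefined for zero-norm vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError(f"length mismatch: {x.shape} vs {y.shape}")
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0.0 or ny == 0.0:
        raise ValidationError("uncentered correlation undefined for a zero vector")
    return float(np.clip(x @ y / (nx * ny), -1.0, 1.0))


def match_predicted_to_measured(
    flux: FluxDistribution, measured: MeasuredFluxSet
) -> ValidationResult:
    """Evaluate each record's mapping on the predicted fluxes.

    AND (series) takes the minimum predicted flux, OR (parallel) the sum;
    nesting is evaluated recursively.  A mapping that references a reaction
    absent from the flux vector is an error (silently dropping records would
    change the reported correlation).
    """
    values = flux.fluxes.to_dict()
    predicted = []
    for rec in measured.records:
        missing = [x for x in rec.mapping.leaves() if x not in values]
        if missing:
            raise ValidationError(
                f"measured record {rec.measured_id!r}: reactions {missing} "
                "not present in the flux distribution"
            )
        predicted.append(evaluate(rec.mapping, values, missing="strict"))
    result = ValidationResult(
        measured_ids=[r.measured_id for r in measured.records],
        predicted=np.array(predicted, dtype=float),
        measured=measured.values(),
        mappings=[r.mapping.to_string() for r in measured.records],
        method=flux.method,
        condition=measured.condition,
    )
    result.correlation = uncentered_pearson(result.predicted, result.measured)
    return result


def expression_flux_correlation(
    rxnexp: ReactionExpression, measured: MeasuredFluxSet
) -> Tuple[float, int]:
    """Correlation between mapped expression and |measured| fluxes.

    Expression values are pushed through the same mapping rules (AND -> min,
    OR -> sum).  Measured values enter as absolute values because abundances
    are nonnegative.  Records whose mapping has no expressed reaction are
    excluded (count returned alongside the correlation).
    """
    g_matched = []
    v_abs = []
    n_excluded = 0
    for rec in measured.records:
        g = evaluate(rec.mapping, rxnexp.values, missing="drop")
        if g is None:
            n_excluded += 1
            continue
        g_matched.append(g)
        v_abs.append(abs(rec.value))
    if n_excluded:
        logger.info(
            "expression/flux correlation: excluded %d records without "
            "expression", n_excluded,
        )
    if len(g_matched) < 2:
        raise ValidationError(
            "fewer than two measured records have mapped expression"
        )
    return uncentered_pearson(g_matched, v_abs), n_excluded


def normalize_to_measured(
    result: ValidationResult,
) -> np.ndarray:
    """Scale the matched predicted vector to the measured vector's norm.

    Predictions carry an arbitrary unit; for side-by-side display they are
    rescaled by ||v_m||/||v_p||.  The uncentered correlation is unchanged.
    """
    np_pred = np.linalg.norm(result.predicted)
    if np_pred == 0.0:
        raise ValidationError("cannot normalize a zero predicted vector")
    return result.predicted * (np.linalg.norm(result.measured) / np_pred)


def correlation_range(
    model: MetabolicModel,
    measured: MeasuredFluxSet,
    lb: Optional[np.ndarray] = None,
    ub: Optional[np.ndarray] = None,
    objective: Optional[str] = None,
    eps_obj: float = 1e-6,
    piece_limit: int = 256,
    tol: float = 1e-8,
) -> Tuple[float, float]:
    """Extremes of the uncentered correlation over an LP's optimal face.

    The optimal face {v : S v = 0, lb <= v <= ub, f'v = z*} of FBA or E-Flux
    contains many flux distributions; this computes the minimum and maximum
    correlation between the matched predicted vector m(v) and the measured
    values attainable on that face.

    m(v) is concave and positively homogeneous (minima and sums of linear
    functions), so it is a minimum over finitely many linear maps M_sigma.
    For each piece selection sigma the face is homogenized with a scale
    variable t (correlation is scale invariant), the piece's linearity
    region is added, the matched vector is capped at unit norm, and the
    linear objective v_m . (M_sigma v) is maximized or minimized — a convex
    program in both directions.  The overall extremes are the best over the
    (few) pieces; enumeration is refused above ``piece_limit`` combinations.
    """
    if lb is None:
        lb = model.lower_bounds
    if ub is None:
        ub = model.upper_bounds
    measured.check_against_model(model)
    n = model.n_reactions
    f = np.zeros(n)
    if objective is None:
        f = np.asarray(model.objective, dtype=float)
        if not np.any(f):
            raise ValueError("no objective available for the optimal face")
    else:
        f[model.reaction_index(objective)] = 1.0

    step1 = solve_lp(f, model.stoichiometry, None, lb, ub)
    z_star = step1.objective
    v_face = step1.x

    rxn_index = {r: j for j, r in enumerate(model.reaction_ids)}
    record_pieces: List[List[np.ndarray]] = []
    total = 1
    for rec in measured.records:
        total *= piece_count(rec.mapping)
        rows = []
        for piece in linear_pieces(rec.mapping):
            row = np.zeros(n)
            for rid, coef in piece.items():
                row[rxn_index[rid]] += coef
            rows.append(row)
        record_pieces.append(rows)
    if total > piece_limit:
        raise ValidationError(
            f"mapping rules have {total} linear pieces (> limit {piece_limit}); "
            "the correlation range for this measured set is not enumerable"
        )

    v_m = measured.values()
    norm_vm = np.linalg.norm(v_m)
    values_full = {r: v_face[j] for r, j in rxn_index.items()}

    best_max: Optional[float] = None
    best_min: Optional[float] = None
    k = len(measured.records)
    for chosen in itertools.product(*[range(len(p)) for p in record_pieces]):
        M = np.vstack([record_pieces[i][c] for i, c in enumerate(chosen)])
        region_rows = []
        for i, c in enumerate(chosen):
            for other, row in enumerate(record_pieces[i]):
                if other != c:
                    region_rows.append(record_pieces[i][c] - row)
        for sense in ("max", "min"):
            corr = _face_cone_extremum(
                model, lb, ub, f, z_star, v_face, M, region_rows, v_m, sense, tol
            )
            if corr is None:
                continue
            if sense == "max":
                best_max = corr if best_max is None else max(best_max, corr)
            else:
                best_min = corr if best_min is None else min(best_min, corr)
    if best_max is None or best_min is None:
        raise ValidationError(
            "no point of the optimal face yields a defined correlation"
        )
    return best_min, best_max


def _face_cone_extremum(
    model, lb, ub, f, z_star, v_face, M, region_rows, v_m, sense, tol
) -> Optional[float]:
    """One convex subproblem of :func:`correlation_range`.

    Variables x = [v, t], t >= 0 the homogenization scale.  Constraints:
    S v = 0; f'v = z* t; lb_j t <= v_j <= ub_j t (finite bounds only);
    region rows (chosen piece is the minimum); ||M v|| <= 1.  Objective:
    +-(v_m' M) v.
    """
    n = model.n_reactions
    k = M.shape[0]
    S = model.stoichiometry
    A_eq = sparse.hstack(
        [sparse.vstack([S, sparse.csr_matrix(f)]),
         sparse.csc_matrix(
             np.concatenate([np.zeros(S.shape[0]), [-z_star]])[:, None]
         )],
        format="csc",
    )
    rows = []
    for j in range(n):
        if np.isfinite(ub[j]):
            r = np.zeros(n + 1)
            r[j] = 1.0
            r[n] = -ub[j]
            rows.append(r)
        if np.isfinite(lb[j]):
            r = np.zeros(n + 1)
            r[j] = -1.0
            r[n] = lb[j]
            rows.append(r)
    for row in region_rows:
        rows.append(np.concatenate([row, [0.0]]))
    A_ub = np.array(rows) if rows else None
    b_ub = np.zeros(len(rows)) if rows else None
    M_ext = np.hstack([M, np.zeros((k, 1))])
    w = np.concatenate([M.T @ v_m, [0.0]])

    lo = np.full(n + 1, -np.inf)
    hi = np.full(n + 1, np.inf)
    lo[n] = 0.0

    m_face = M @ v_face
    scale = 0.5 / np.linalg.norm(m_face) if np.linalg.norm(m_face) > 1e-12 else 1.0
    x0 = np.concatenate([v_face * scale, [scale]])
    # x0 may violate region rows; fall back to the origin (always feasible)
    if A_ub is not None and np.any(A_ub @ x0 > 1e-9):
        x0 = np.zeros(n + 1)
    try:
        res = maximize_linear_with_norm_cap(
            w, A_eq, lo, hi, A_ub=A_ub, b_ub=b_ub, norm_matrix=M_ext,
            maximize=(sense == "max"), tol=tol, x0=x0,
        )
    except SolverError as exc:
        logger.warning("correlation-range subproblem failed (%s): %s", sense, exc)
        res = None
    if res is not None:
        v = res.x[:n]
        m_v = M @ v
        # the cone device is exact when the norm cap is active at the
        # optimum; otherwise the extremum has the unfavorable sign and the
        # optimizer collapses towards the cone apex
        if np.linalg.norm(m_v) > 0.5:
            return float(np.clip(
                res.objective / (np.linalg.norm(m_v) * np.linalg.norm(v_m)),
                -1.0, 1.0,
            ))
    return _face_direct_extremum(
        model, lb, ub, f, z_star, v_face, M, region_rows, v_m, sense
    )


def _face_direct_extremum(
    model, lb, ub, f, z_star, v_face, M, region_rows, v_m, sense
) -> Optional[float]:
    """Ratio optimization directly over the face polytope.

    Used when the homogenized convex program degenerates (every face point
    correlates with the measured vector in the direction being pushed away
    from).  The correlation is optimized locally from several deterministic
    starting vertices of the face; exactness on low-degree-of-freedom
    fixtures is checked against the grid oracle in the test suite.
    """
    from scipy.optimize import LinearConstraint, minimize

    n = model.n_reactions
    S_dense = np.asarray(model.stoichiometry.todense())
    A_rows = np.vstack([S_dense, f[None, :]])
    b_rows = np.concatenate([np.zeros(S_dense.shape[0]), [z_star]])
    finite = np.concatenate([np.abs(lb[np.isfinite(lb)]), np.abs(ub[np.isfinite(ub)]),
                             np.abs(v_face), [1.0]])
    big = 10.0 * float(np.max(finite))
    lo = np.where(np.isfinite(lb), lb, -big)
    hi = np.where(np.isfinite(ub), ub, big)
    norm_vm = np.linalg.norm(v_m)
    sign = -1.0 if sense == "max" else 1.0

    def ratio(v):
        m_v = M @ v
        nm = np.linalg.norm(m_v)
        if nm < 1e-12:
            return 0.0
        return sign * float(m_v @ v_m) / (nm * norm_vm)

    constraints = [LinearConstraint(A_rows, b_rows, b_rows)]
    if region_rows:
        R = np.array(region_rows)
        constraints.append(LinearConstraint(R, -np.inf, np.zeros(len(region_rows))))
    # deterministic multistart: the LP vertex plus extreme points of the
    # face in random directions
    rng = np.random.default_rng(12345)
    starts = [v_face]
    for _ in range(8):
        c = rng.standard_normal(n)
        try:
            res = solve_lp(c, sparse.csr_matrix(A_rows), b_rows, lo, hi)
            starts.append(res.x)
        except SolverError:
            continue
    best = None
    for x0 in starts:
        try:
            res = minimize(
                ratio, x0, method="SLSQP",
                bounds=np.column_stack([lo, hi]),
                constraints=[
                    {"type": "eq", "fun": lambda v: A_rows @ v - b_rows},
                ] + ([{"type": "ineq",
                       "fun": lambda v: -(np.array(region_rows) @ v)}]
                     if region_rows else []),
                options={"maxiter": 300, "ftol": 1e-12},
            )
        except Exception:
            continue
        if not res.success:
            continue
        v = res.x
        if np.linalg.norm(M @ v) < 1e-9:
            continue
        val = sign * ratio(v)
        if best is None or (sense == "max" and val > best) or (
            sense == "min" and val < best
        ):
            best = val
    if best is None:
        return None
    return float(np.clip(best, -1.0, 1.0))


def summarize_conditions(correlations: Sequence[float]) -> Dict[str, float]:
    """Arithmetic mean and standard deviation across conditions."""
    arr = np.asarray(list(correlations), dtype=float)
    return {
        "mean": float(arr.mean()),
        "sd": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
        "n": int(arr.size),
    }


def plot_flux_comparison(result: ValidationResult, path) -> None:
    """Grouped bar chart of measured vs norm-scaled predicted fluxes."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    scaled = normalize_to_measured(result)
    x = np.arange(len(result.measured_ids))
    fig, ax = plt.subplots(figsize=(max(6, 0.5 * len(x)), 4))
    ax.bar(x - 0.2, result.measured, width=0.4, label="measured")
    ax.bar(x + 0.2, scaled, width=0.4, label=f"predicted ({result.method})")
    ax.set_xticks(x)
    ax.set_xticklabels(result.measured_ids, rotation=90, fontsize=7)
    ax.set_ylabel("flux (measured units)")
    title = f"r = {result.correlation:.4f}" if result.correlation is not None else ""
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
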