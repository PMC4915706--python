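"""Expression profiles, GPR evaluation, E-Flux bounds and SPOT weights.

A single-condition expression profile (gene -> nonnegative abundance,
arbitrary units) is mapped onto reactions through GPR rules: enzyme-complex
subunits (AND) take the minimum abundance, isozymes (OR) sum.  The
per-reaction value g_j then either caps the flux (E-Flux bounds) or weights
the flux in the correlation objective (SPOT), depending on the method.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import sparse

from .boolexpr import BoolExpr, evaluate
from .model import INF, MetabolicModel
from .template import TemplateModel

logger = logging.getLogger(__name__)


@dataclass
class ExpressionProfile:
    """Gene -> abundance map for one condition (arbitrary units, >= 0)."""

    values: Dict[str, float]
    condition: str = ""
    case_fold: bool = False

    def __post_init__(self):
        if self.case_fold:
            self.values = {g.lower(): v for g, v in self.values.items()}
        for g, v in self.values.items():
            if v < 0:
                raise ValueError(f"negative abundance for gene {g!r}: {v}")

    def get(self, gene: str) -> Optional[float]:
        return self.values.get(gene.lower() if self.case_fold else gene)


def read_expression_table(
    path,
    gene_col=0,
    value_col=1,
    sep: Optional[str] = None,
    condition: str = "",
    case_fold: bool = False,
) -> ExpressionProfile:
    """Read a delimited gene/abundance table.

    ``gene_col``/``value_col`` select columns by name or 0-based position.
    Duplicate gene rows are aggregated by mean (count logged); negative or
    non-numeric abundances are rejected with the offending row number.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    header = 0
    first = pd.read_csv(path, sep=sep, header=None, nrows=1, comment="#")
    # headerless detection: second column of first row numeric -> no header
    try:
        float(first.iloc[0, value_col if isinstance(value_col, int) else 1])
        header = None
    except (TypeError, ValueError):
        header = 0
    df = pd.read_csv(path, sep=sep, header=header, comment="#")
    genes = (df[gene_col] if not isinstance(gene_col, int) else df.iloc[:, gene_col]).astype(str)
    raw = df[value_col] if not isinstance(value_col, int) else df.iloc[:, value_col]
    values = pd.to_numeric(raw, errors="coerce")
    bad = values.isna() & raw.notna()
    if bad.any():
        row = int(np.nonzero(bad.to_numpy())[0][0])
        raise ValueError(
            f"{path}: non-numeric abundance {raw.iloc[row]!r} in data row {row}"
        )
    neg = values < 0
    if neg.any():
        row = int(np.nonzero(neg.to_numpy())[0][0])
        raise ValueError(
            f"{path}: negative abundance {values.iloc[row]} in data row {row}"
        )
    frame = pd.DataFrame({"gene": genes, "value": values}).dropna()
    n_dup = int(frame.duplicated("gene").sum())
    if n_dup:
        logger.info("%s: aggregated %d duplicate gene rows by mean", path, n_dup)
    agg = frame.groupby("gene", sort=False)["value"].mean()
    return ExpressionProfile(
        values=dict(agg), condition=condition or path.stem, case_fold=case_fold
    )


@dataclass
class ReactionExpression:
    """Per-reaction expression values; reactions without usable data absent."""

    values: Dict[str, float]
    condition: str = ""
    n_with_gpr: int = 0
    n_mapped: int = 0

    def get(self, reaction_id: str) -> Optional[float]:
        return self.values.get(reaction_id)

    def to_frame(self, model: MetabolicModel) -> pd.DataFrame:
        rows = []
        for rid, g in zip(model.reaction_ids, model.gpr):
            if g is None:
                status = "no_gpr"
            elif rid in self.values:
                status = "mapped"
            else:
                status = "unmeasured"
            rows.append((rid, self.values.get(rid, ""), status))
        return pd.DataFrame(rows, columns=["reaction_id", "value", "rule_status"])


def reaction_expression(
    model: MetabolicModel,
    profile: ExpressionProfile,
    missing: str = "drop",
) -> ReactionExpression:
    """Evaluate every GPR against the profile (AND -> min, OR -> sum).

    ``missing`` is the partial-measurement policy (see
    :func:`fluxinfer.boolexpr.evaluate`).  Reactions without a GPR, or whose
    rule has no measured gene, are absent from the result.
    """
    values: Dict[str, float] = {}
    n_with_gpr = 0
    lookup = profile.values
    for rid, expr in zip(model.reaction_ids, model.gpr):
        if expr is None:
            continue
        n_with_gpr += 1
        if profile.case_fold:
            vals = {leaf: profile.get(leaf) for leaf in expr.leaves()}
            vals = {k: v for k, v in vals.items() if v is not None}
            g = evaluate(expr, vals, missing)
        else:
            g = evaluate(expr, lookup, missing)
        if g is not None:
            values[rid] = g
    return ReactionExpression(
        values=values,
        condition=profile.condition,
        n_with_gpr=n_with_gpr,
        n_mapped=len(values),
    )


@dataclass
class EFluxBounds:
    """Per-reaction flux bounds after expression capping."""

    lower: np.ndarray
    upper: np.ndarray
    mapped: np.ndarray  # bool mask: True where expression replaced template bounds


def eflux_bounds(template: TemplateModel, rxnexp: ReactionExpression) -> EFluxBounds:
    """Cap template bounds with per-reaction expression.

    For a reaction with available g_j: upper bound g_j where the template
    allowed forward flux (else 0); lower bound -g_j where it allowed reverse
    flux (else 0).  Reactions without usable expression keep their template
    bounds so the model is not constrained unnecessarily.
    """
    lb = template.lower_bounds.copy()
    ub = template.upper_bounds.copy()
    mapped = np.zeros(template.n_reactions, dtype=bool)
    for j, rid in enumerate(template.reaction_ids):
        g = rxnexp.get(rid)
        if g is None:
            continue
        mapped[j] = True
        ub[j] = g if template.upper_bounds[j] > 0 else 0.0
        lb[j] = -g if template.lower_bounds[j] < 0 else 0.0
    return EFluxBounds(lower=lb, upper=ub, mapped=mapped)


@dataclass
class Decomposition:
    """Reversible-splitting bookkeeping for SPOT.

    Columns are ordered [irreversible/forward-oriented | reversible forward
    copies | reversible backward copies].  ``orig_index`` maps each column
    back to its source reaction; ``sign`` is the orientation factor applied
    when recombining (-1 for flipped backward-only reactions); ``kind`` is
    one of "fwd", "rev_f", "rev_b".
    """

    S_bar: sparse.csc_matrix
    weights: np.ndarray
    orig_index: np.ndarray
    sign: np.ndarray
    kind: List[str]
    upper: np.ndarray  # 0 for dead reactions, +inf otherwise
    n_reactions: int

    def recombine(self, v_bar: np.ndarray) -> np.ndarray:
        v = np.zeros(self.n_reactions)
        for col, val in enumerate(v_bar):
            j = self.orig_index[col]
            if self.kind[col] == "rev_b":
                v[j] -= val
            else:
                v[j] += self.sign[col] * val
        return v


def spot_weights(template: TemplateModel, rxnexp: ReactionExpression) -> Decomposition:
    """Decompose reversible reactions and attach expression weights.

    Backward-only reactions (template upper bound 0) are flipped into
    forward orientation (column negated) so all variables are nonnegative;
    their expression weight stays g_j and the recombined flux is reported
    with the original sign.  Reversible reactions contribute identical
    weights to their forward and backward copies.  Reactions without usable
    expression get weight 0.
    """
    S = template.stoichiometry.tocsc()
    cols: List[sparse.csc_matrix] = []
    weights: List[float] = []
    orig: List[int] = []
    sign: List[float] = []
    kind: List[str] = []
    upper: List[float] = []
    rev: List[int] = []
    for j, rid in enumerate(template.reaction_ids):
        lo, hi = template.lower_bounds[j], template.upper_bounds[j]
        g = rxnexp.get(rid)
        w = float(g) if g is not None else 0.0
        if lo < 0 and hi > 0:
            rev.append(j)
            continue
        if hi <= 0 and lo < 0:
            # backward-only: flip into forward orientation
            cols.append(-S[:, j])
            weights.append(w)
            orig.append(j)
            sign.append(-1.0)
            kind.append("fwd")
            upper.append(INF)
        else:
            cols.append(S[:, j])
            weights.append(w)
            orig.append(j)
            sign.append(1.0)
            kind.append("fwd")
            upper.append(INF if hi > 0 else 0.0)
    for j in rev:
        cols.append(S[:, j])
        g = rxnexp.get(template.reaction_ids[j])
        weights.append(float(g) if g is not None else 0.0)
        orig.append(j)
        sign.append(1.0)
        kind.append("rev_f")
        upper.append(INF)
    for j in rev:
        cols.append(-S[:, j])
        g = rxnexp.get(template.reaction_ids[j])
        weights.append(float(g) if g is not None else 0.0)
        orig.append(j)
        sign.append(1.0)
        kind.append("rev_b")
        upper.append(INF)
    S_bar = sparse.hstack(cols, format="csc") if cols else sparse.csc_matrix((template.n_metabolites, 0))
    return Decomposition(
        S_bar=S_bar,
        weights=np.asarray(weights, dtype=float),
        orig_index=np.asarray(orig, dtype=int),
        sign=np.asarray(sign, dtype=float),
        kind=kind,
        upper=np.asarray(upper, dtype=float),
        n_reactions=template.n_reactions,
    )
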