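"""Stoichiometric model container and SBML import.

The in-memory representation is deliberately small: an ordered sparse
stoichiometric matrix, per-reaction bounds and objective coefficients, and a
parsed GPR tree per reaction.  Unbounded fluxes are represented with IEEE
infinities (never big-M constants); solver adapters translate them to
solver-native unboundedness.  Identifiers are opaque strings — no prefix
stripping is applied on import.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import sparse

from .boolexpr import BoolExpr, parse as parse_rule

logger = logging.getLogger(__name__)

INF = math.inf


class ModelError(ValueError):
    pass


@dataclass
class MetabolicModel:
    """A stoichiometric network with bounds, objective and GPR rules.

    ``stoichiometry`` is an m x n scipy sparse matrix (metabolites x
    reactions); ``lower_bounds``/``upper_bounds`` may contain +-inf.
    """

    metabolite_ids: List[str]
    reaction_ids: List[str]
    stoichiometry: sparse.csc_matrix
    lower_bounds: np.ndarray
    upper_bounds: np.ndarray
    objective: np.ndarray
    gpr: List[Optional[BoolExpr]]
    metabolite_formulas: List[Optional[str]] = field(default_factory=list)
    compartments: List[Optional[str]] = field(default_factory=list)
    model_id: str = "model"

    def __post_init__(self):
        m, n = self.stoichiometry.shape
        if len(self.metabolite_ids) != m:
            raise ModelError("metabolite count does not match stoichiometry rows")
        for name, arr_len in (
            ("reaction_ids", len(self.reaction_ids)),
            ("lower_bounds", len(self.lower_bounds)),
            ("upper_bounds", len(self.upper_bounds)),
            ("objective", len(self.objective)),
            ("gpr", len(self.gpr)),
        ):
            if arr_len != n:
                raise ModelError(f"{name} length {arr_len} != column count {n}")
        if len(set(self.reaction_ids)) != n:
            raise ModelError("duplicate reaction identifiers")
        if not self.metabolite_formulas:
            self.metabolite_formulas = [None] * m
        if not self.compartments:
            self.compartments = [None] * m
        self.lower_bounds = np.asarray(self.lower_bounds, dtype=float)
        self.upper_bounds = np.asarray(self.upper_bounds, dtype=float)
        self.objective = np.asarray(self.objective, dtype=float)
        bad = np.nonzero(self.lower_bounds > self.upper_bounds)[0]
        if bad.size:
            j = int(bad[0])
            raise ModelError(
                f"reaction {self.reaction_ids[j]!r}: lower bound "
                f"{self.lower_bounds[j]} exceeds upper bound {self.upper_bounds[j]}"
            )

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    def reaction_index(self, reaction_id: str) -> int:
        try:
            return self.reaction_ids.index(reaction_id)
        except ValueError:
            raise KeyError(f"unknown reaction {reaction_id!r}") from None

    def copy(self) -> "MetabolicModel":
        return replace(
            self,
            stoichiometry=self.stoichiometry.copy(),
            lower_bounds=self.lower_bounds.copy(),
            upper_bounds=self.upper_bounds.copy(),
            objective=self.objective.copy(),
            gpr=list(self.gpr),
            metabolite_ids=list(self.metabolite_ids),
            reaction_ids=list(self.reaction_ids),
            metabolite_formulas=list(self.metabolite_formulas),
            compartments=list(self.compartments),
        )


def read_sbml(path) -> MetabolicModel:
    """Load an SBML Level 2 / Level 3 (+fbc) file.

    GPRs are taken from the fbc ``geneProductAssociation`` when present,
    falling back to legacy ``GENE_ASSOCIATION`` notes.  Bounds missing from
    the file default to (-inf, +inf) for reversible and (0, +inf) for
    irreversible reactions.  Identifiers are kept verbatim (no ``R_``/``M_``
    prefix munging).
    """
    import cobra
    from cobra.io import read_sbml_model

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cfg = cobra.Configuration()
    old_bounds = tuple(cfg.bounds)
    cfg.bounds = (-INF, INF)
    try:
        try:
            cm = read_sbml_model(str(path), f_replace={})
        except Exception as exc:  # libsbml/cobra raise several error types
            raise ModelError(f"could not parse SBML file {path}: {exc}") from exc
    finally:
        cfg.bounds = old_bounds

    explicit = _reactions_with_explicit_bounds(path)
    met_index = {m.id: i for i, m in enumerate(cm.metabolites)}
    n = len(cm.reactions)
    rows: List[int] = []
    cols: List[int] = []
    data: List[float] = []
    lb = np.empty(n)
    ub = np.empty(n)
    obj = np.zeros(n)
    gprs: List[Optional[BoolExpr]] = []
    rxn_ids: List[str] = []
    for j, r in enumerate(cm.reactions):
        rxn_ids.append(r.id)
        lb[j] = r.lower_bound
        ub[j] = r.upper_bound
        if r.id in explicit and not explicit[r.id][1]:
            # no explicit bounds in the file: default from the SBML
            # reversible flag, (0, +inf) when irreversible
            lb[j] = -INF if explicit[r.id][0] else 0.0
            ub[j] = INF
        obj[j] = r.objective_coefficient
        for met, coef in r.metabolites.items():
            rows.append(met_index[met.id])
            cols.append(j)
            data.append(float(coef))
        rule = r.gene_reaction_rule
        gprs.append(parse_rule(rule) if rule and rule.strip() else None)
    S = sparse.csc_matrix(
        (data, (rows, cols)), shape=(len(cm.metabolites), n), dtype=float
    )
    return MetabolicModel(
        metabolite_ids=[m.id for m in cm.metabolites],
        reaction_ids=rxn_ids,
        stoichiometry=S,
        lower_bounds=lb,
        upper_bounds=ub,
        objective=obj,
        gpr=gprs,
        metabolite_formulas=[m.formula or None for m in cm.metabolites],
        compartments=[m.compartment or None for m in cm.metabolites],
        model_id=cm.id or path.stem,
    )


def _reactions_with_explicit_bounds(path) -> Dict[str, Tuple[bool, bool]]:
    """Map reaction id -> (reversible flag, has explicit bounds) from SBML.

    Explicit bounds are fbc lower/upper flux-bound references (L3) or
    LOWER_BOUND/UPPER_BOUND kinetic-law parameters (legacy L2).
    """
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    sbml_model = doc.getModel()
    out: Dict[str, Tuple[bool, bool]] = {}
    if sbml_model is None:
        return out
    for r in sbml_model.getListOfReactions():
        has_bounds = False
        fbc = r.getPlugin("fbc")
        if fbc is not None and (
            fbc.isSetLowerFluxBound() or fbc.isSetUpperFluxBound()
        ):
            has_bounds = True
        kl = r.getKineticLaw()
        if kl is not None and (
            kl.getParameter("LOWER_BOUND") or kl.getParameter("UPPER_BOUND")
        ):
            has_bounds = True
        out[r.getId()] = (bool(r.getReversible()), has_bounds)
    return out


def parse_gpr(rule_text: str) -> BoolExpr:
    """Parse a GPR rule string (AND binds tighter than OR)."""
    return parse_rule(rule_text)


def find_exchange_reactions(model: MetabolicModel) -> Dict[str, str]:
    """Boundary reactions: columns touching exactly one metabolite.

    Returns an ordered ``{reaction_id: metabolite_id}`` map.
    """
    S = model.stoichiometry.tocsc()
    out: Dict[str, str] = {}
    for j, rid in enumerate(model.reaction_ids):
        start, end = S.indptr[j], S.indptr[j + 1]
        nz = [S.indices[k] for k in range(start, end) if S.data[k] != 0.0]
        if len(nz) == 1:
            out[rid] = model.metabolite_ids[nz[0]]
    return out


def export_tables(model: MetabolicModel, directory) -> Dict[str, Path]:
    """Write the model as delimited text tables (reactions, stoichiometry,
    metabolites).  This is the only model export format; modified models are
    not written back to SBML."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rxn = pd.DataFrame(
        {
            "reaction_id": model.reaction_ids,
            "lower_bound": model.lower_bounds,
            "upper_bound": model.upper_bounds,
            "objective": model.objective,
            "gpr": [g.to_string() if g is not None else "" for g in model.gpr],
        }
    )
    coo = model.stoichiometry.tocoo()
    sto = pd.DataFrame(
        {
            "metabolite_id": [model.metabolite_ids[i] for i in coo.row],
            "reaction_id": [model.reaction_ids[j] for j in coo.col],
            "coefficient": coo.data,
        }
    )
    met = pd.DataFrame(
        {
            "metabolite_id": model.metabolite_ids,
            "formula": [f or "" for f in model.metabolite_formulas],
            "compartment": [c or "" for c in model.compartments],
        }
    )
    paths = {}
    for name, frame in (("reactions", rxn), ("stoichiometry", sto), ("metabolites", met)):
        p = directory / f"{name}.tsv"
        frame.to_csv(p, sep="\t", index=False)
        paths[name] = p
    return paths


def import_tables(directory) -> MetabolicModel:
    """Inverse of :func:`export_tables` (used for round-trip checks)."""
    directory = Path(directory)
    rxn = pd.read_csv(directory / "reactions.tsv", sep="\t", keep_default_na=False)
    sto = pd.read_csv(directory / "stoichiometry.tsv", sep="\t", keep_default_na=False)
    met = pd.read_csv(directory / "metabolites.tsv", sep="\t", keep_default_na=False)
    met_ids = list(met["metabolite_id"].astype(str))
    rxn_ids = list(rxn["reaction_id"].astype(str))
    mi = {m: i for i, m in enumerate(met_ids)}
    ri = {r: j for j, r in enumerate(rxn_ids)}
    S = sparse.csc_matrix(
        (
            sto["coefficient"].astype(float),
            (
                [mi[m] for m in sto["metabolite_id"].astype(str)],
                [ri[r] for r in sto["reaction_id"].astype(str)],
            ),
        ),
        shape=(len(met_ids), len(rxn_ids)),
        dtype=float,
    )
    return MetabolicModel(
        metabolite_ids=met_ids,
        reaction_ids=rxn_ids,
        stoichiometry=S,
        lower_bounds=rxn["lower_bound"].astype(float).to_numpy(),
        upper_bounds=rxn["upper_bound"].astype(float).to_numpy(),
        objective=rxn["objective"].astype(float).to_numpy(),
        gpr=[parse_rule(g) if g else None for g in rxn["gpr"].astype(str)],
        metabolite_formulas=[f or None for f in met["formula"].astype(str)],
        compartments=[c or None for c in met["compartment"].astype(str)],
    )
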