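"""Template model construction.

Transcript abundances come in arbitrary units, so using them as flux bounds
on a model whose other bounds carry mmol/gDW/h units would either fail to
constrain anything or constrain everything.  The template construction
removes all numeric bound information from the genome-scale model — every
bound becomes 0 or +-infinity — while keeping stoichiometry, reversibility
and GPR structure.  Two variants encode the carbon-source knowledge:

* DC ("determined carbon source"): the named carbon-source uptake is opened
  to -infinity.
* AC ("all possible carbon sources"): every exchange whose boundary
  metabolite contains carbon (and is not excluded) is opened.

Inorganic exchanges that were open in the original model stay open because
the relaxation maps any negative lower bound to -infinity.
"""

from __future__ import annotations

import difflib
import logging
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np

from .model import INF, MetabolicModel, find_exchange_reactions

logger = logging.getLogger(__name__)

#: Boundary-metabolite formulas never opened as carbon sources by default:
#: fully oxidized one-carbon inorganics that heterotrophs cannot grow on.
DEFAULT_EXCLUDE_FORMULAS = frozenset({"CO2", "HCO3", "CO3", "H2CO3"})

_ELEMENT_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def carbon_count(formula: str) -> int:
    """Number of carbon atoms in an elemental formula string."""
    total = 0
    for element, count in _ELEMENT_RE.findall(formula):
        if element == "C":
            total += int(count) if count else 1
    return total


@dataclass
class TemplateModel(MetabolicModel):
    """A bound-relaxed model: every bound is exactly 0, -inf or +inf."""

    template_kind: Optional[str] = None  # "DC", "AC" or None (bare relaxation)
    carbon_sources_opened: List[str] = field(default_factory=list)


def relax_bounds(model: MetabolicModel) -> TemplateModel:
    """Relax every bound to {0, -inf, +inf}.

    lower: 0 if it was nonnegative, else -inf; upper: +inf if it was
    positive, else 0.  Maintenance floors (e.g. a positive ATPM lower bound)
    are therefore discarded.  Idempotent, and the zero flux vector is
    feasible in the result.
    """
    lb = np.where(model.lower_bounds >= 0.0, 0.0, -INF)
    ub = np.where(model.upper_bounds > 0.0, INF, 0.0)
    return TemplateModel(
        metabolite_ids=list(model.metabolite_ids),
        reaction_ids=list(model.reaction_ids),
        stoichiometry=model.stoichiometry.copy(),
        lower_bounds=lb,
        upper_bounds=ub,
        objective=model.objective.copy(),
        gpr=list(model.gpr),
        metabolite_formulas=list(model.metabolite_formulas),
        compartments=list(model.compartments),
        model_id=model.model_id,
        template_kind=None,
        carbon_sources_opened=[],
    )


def identify_carbon_sources(
    model: MetabolicModel,
    exclude: Iterable[str] = (),
    exclude_formulas: Iterable[str] = DEFAULT_EXCLUDE_FORMULAS,
) -> List[str]:
    """Exchange reactions whose boundary metabolite contains carbon.

    ``exclude`` lists metabolite identifiers to skip; ``exclude_formulas``
    skips by exact formula match (CO2-like species by default).  Boundary
    metabolites without a formula are skipped with a warning.
    """
    exclude = set(exclude)
    exclude_formulas = set(exclude_formulas)
    met_index = {m: i for i, m in enumerate(model.metabolite_ids)}
    out: List[str] = []
    for rxn_id, met_id in find_exchange_reactions(model).items():
        formula = model.metabolite_formulas[met_index[met_id]]
        if formula is None:
            logger.warning(
                "exchange %s: metabolite %s has no formula; skipped as a "
                "potential carbon source",
                rxn_id,
                met_id,
            )
            continue
        if met_id in exclude or formula in exclude_formulas:
            continue
        if carbon_count(formula) >= 1:
            out.append(rxn_id)
    return out


def build_template(
    model: MetabolicModel,
    kind: str,
    carbon_source: Optional[str] = None,
    exclude: Iterable[str] = (),
    exclude_formulas: Iterable[str] = DEFAULT_EXCLUDE_FORMULAS,
    carbon_sources: Optional[Sequence[str]] = None,
) -> TemplateModel:
    """Build a DC or AC template model.

    ``kind`` is "DC" (open the single named ``carbon_source`` exchange) or
    "AC" (open every identified carbon-source exchange).  ``carbon_sources``
    overrides formula-based detection with an explicit exchange-reaction
    list (e.g. a curated list shipped with a model).
    """
    kind = kind.upper()
    if kind not in ("DC", "AC"):
        raise ValueError(f"template kind must be 'DC' or 'AC', got {kind!r}")
    template = relax_bounds(model)
    template.template_kind = kind
    if kind == "DC":
        if carbon_source is None:
            raise ValueError("DC template requires a carbon_source exchange id")
        if carbon_source not in template.reaction_ids:
            near = difflib.get_close_matches(
                carbon_source, template.reaction_ids, n=3
            )
            hint = f"; did you mean {near}?" if near else ""
            raise KeyError(
                f"carbon source reaction {carbon_source!r} not in model{hint}"
            )
        j = template.reaction_index(carbon_source)
        template.lower_bounds[j] = -INF
        template.carbon_sources_opened = [carbon_source]
    else:
        if carbon_sources is None:
            carbon_sources = identify_carbon_sources(
                model, exclude=exclude, exclude_formulas=exclude_formulas
            )
        opened = []
        for rxn_id in carbon_sources:
            j = template.reaction_index(rxn_id)
            template.lower_bounds[j] = -INF
            opened.append(rxn_id)
        template.carbon_sources_opened = opened
    return template
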