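"""Boolean AND/OR expression trees over string identifiers.

One grammar serves two purposes in this package:

* gene-protein-reaction (GPR) rules, where leaves are gene identifiers
  (AND = subunits of an enzyme complex, OR = isozymes), and
* measured-flux mapping rules, where leaves are model reaction identifiers
  (AND = consecutive reactions in series, OR = parallel identical reactions).

Both are evaluated with the same arithmetic: AND nodes take the minimum of
their children (the limiting component / rate-limiting step), OR nodes take
the sum (capacities of alternatives add).  AND binds tighter than OR;
parentheses override.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Dict, Iterator, List, Optional, Sequence, Tuple


class BoolExprError(ValueError):
    """Raised for malformed rule text (position is 0-based character offset)."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


@dataclass(frozen=True)
class BoolExpr:
    """Base class for rule nodes."""

    def leaves(self) -> Iterator[str]:
        raise NotImplementedError

    def to_string(self) -> str:
        raise NotImplementedError


@dataclass(frozen=True)
class Leaf(BoolExpr):
    name: str

    def leaves(self) -> Iterator[str]:
        yield self.name

    def to_string(self) -> str:
        return self.name


@dataclass(frozen=True)
class And(BoolExpr):
    children: Tuple[BoolExpr, ...]

    def __post_init__(self):
        # flatten associative nesting so equal rules compare equal
        flat: List[BoolExpr] = []
        for c in self.children:
            flat.extend(c.children if isinstance(c, And) else (c,))
        object.__setattr__(self, "children", tuple(flat))

    def leaves(self) -> Iterator[str]:
        for c in self.children:
            yield from c.leaves()

    def to_string(self) -> str:
        parts = []
        for c in self.children:
            s = c.to_string()
            if isinstance(c, Or):
                s = f"({s})"
            parts.append(s)
        return " and ".join(parts)


@dataclass(frozen=True)
class Or(BoolExpr):
    children: Tuple[BoolExpr, ...]

    def __post_init__(self):
        flat: List[BoolExpr] = []
        for c in self.children:
            flat.extend(c.children if isinstance(c, Or) else (c,))
        object.__setattr__(self, "children", tuple(flat))

    def leaves(self) -> Iterator[str]:
        for c in self.children:
            yield from c.leaves()

    def to_string(self) -> str:
        return " or ".join(c.to_string() for c in self.children)


_TOKEN_RE = re.compile(r"\s*(\(|\)|[^\s()]+)")


def _tokenize(text: str) -> List[Tuple[str, int]]:
    tokens: List[Tuple[str, int]] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            break
        tokens.append((m.group(1), m.start(1)))
        pos = m.end()
    return tokens


def parse(text: str) -> BoolExpr:
    """Parse rule text into a :class:`BoolExpr` tree.

    ``and``/``or`` are case-insensitive keywords; ``&``/``|`` are accepted as
    synonyms.  AND binds tighter than OR.  Raises :class:`BoolExprError` with
    a character position on malformed input.
    """
    tokens = _tokenize(text)
    if not tokens:
        raise BoolExprError("empty rule", 0)
    expr, idx = _parse_or(tokens, 0, text)
    if idx != len(tokens):
        raise BoolExprError(f"unexpected token {tokens[idx][0]!r}", tokens[idx][1])
    return expr


def _is_kw(token: str, kw: str) -> bool:
    return token.lower() == kw or token == {"and": "&", "or": "|"}[kw]


def _parse_or(tokens, idx, text):
    children = []
    child, idx = _parse_and(tokens, idx, text)
    children.append(child)
    while idx < len(tokens) and _is_kw(tokens[idx][0], "or"):
        idx += 1
        child, idx = _parse_and(tokens, idx, text)
        children.append(child)
    if len(children) == 1:
        return children[0], idx
    return Or(tuple(children)), idx


def _parse_and(tokens, idx, text):
    children = []
    child, idx = _parse_atom(tokens, idx, text)
    children.append(child)
    while idx < len(tokens) and _is_kw(tokens[idx][0], "and"):
        idx += 1
        child, idx = _parse_atom(tokens, idx, text)
        children.append(child)
    if len(children) == 1:
        return children[0], idx
    return And(tuple(children)), idx


def _parse_atom(tokens, idx, text):
    if idx >= len(tokens):
        raise BoolExprError("missing operand at end of rule", len(text))
    tok, pos = tokens[idx]
    if tok == "(":
        expr, idx = _parse_or(tokens, idx + 1, text)
        if idx >= len(tokens) or tokens[idx][0] != ")":
            raise BoolExprError("unbalanced parenthesis", pos)
        return expr, idx + 1
    if tok == ")":
        raise BoolExprError("unexpected ')'", pos)
    if tok.lower() in ("and", "or") or tok in ("&", "|"):
        raise BoolExprError(f"missing operand before {tok!r}", pos)
    return Leaf(tok), idx + 1


def evaluate(
    expr: BoolExpr,
    values: Dict[str, float],
    missing: str = "drop",
) -> Optional[float]:
    """Evaluate a rule with AND -> min, OR -> sum.

    ``values`` maps leaf identifiers to nonnegative numbers; leaves absent
    from the map are unmeasured.  ``missing`` selects the policy for
    partially measured rules:

    * ``"drop"``: unmeasured leaves are dropped — an OR sums its measured
      children, an AND takes the minimum over its measured children; a node
      with no measured descendant is unavailable.
    * ``"strict"``: any unmeasured leaf anywhere makes the whole rule
      unavailable.

    Returns the numeric value, or ``None`` when the rule is unavailable.
    """
    if missing not in ("drop", "strict"):
        raise ValueError(f"unknown missing-policy {missing!r}")
    if isinstance(expr, Leaf):
        return values.get(expr.name)
    vals = [evaluate(c, values, missing) for c in expr.children]
    if missing == "strict" and any(v is None for v in vals):
        return None
    present = [v for v in vals if v is not None]
    if not present:
        return None
    if isinstance(expr, And):
        return min(present)
    return sum(present)


def linear_pieces(expr: BoolExpr) -> List[Dict[str, float]]:
    """Decompose the min/sum evaluation into linear pieces.

    The evaluation ``v -> evaluate(expr, v)`` is a concave, piecewise-linear,
    positively homogeneous function: a minimum over a finite set of linear
    combinations of the leaves.  This returns that set, each piece as a
    ``{leaf: coefficient}`` map, so that

        evaluate(expr, v) == min(sum(c*v[g] for g, c in piece.items())
                                 for piece in linear_pieces(expr))

    for fully measured ``v``.  AND = union of children's piece sets; OR =
    all cross-sums of children's pieces.  Piece counts multiply across OR
    nodes, so callers should bound the size for deep rules.
    """
    if isinstance(expr, Leaf):
        return [{expr.name: 1.0}]
    if isinstance(expr, And):
        pieces: List[Dict[str, float]] = []
        for c in expr.children:
            pieces.extend(linear_pieces(c))
        return pieces
    # Or: cross-product sums
    acc: List[Dict[str, float]] = [{}]
    for c in expr.children:
        child_pieces = linear_pieces(c)
        nxt: List[Dict[str, float]] = []
        for base in acc:
            for p in child_pieces:
                merged = dict(base)
                for k, coef in p.items():
                    merged[k] = merged.get(k, 0.0) + coef
                nxt.append(merged)
        acc = nxt
    return acc


def piece_count(expr: BoolExpr) -> int:
    """Number of linear pieces of ``expr`` without materializing them."""
    if isinstance(expr, Leaf):
        return 1
    if isinstance(expr, And):
        return sum(piece_count(c) for c in expr.children)
    n = 1
    for c in expr.children:
        n *= piece_count(c)
    return n
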