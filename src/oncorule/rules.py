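"""Dichotomous classifier rules over gene-expression profiles.

A rule is an algebraic/logical expression tree whose terminals are gene
symbols or numeric constants.  Evaluating the tree on a patient's
normalized expression profile yields a real-valued score; comparing that
score against the rule's *slice point* dichotomizes patients into
``high``/``low`` recurrence-risk groups.  The grammar is deliberately
constrained (a fixed operator set, a cap on the number of distinct genes
and on tree depth) so that evolved rules stay small and interpretable.

Boolean sub-expressions are encoded numerically (true = 1.0, false =
0.0, any value > 0 counts as true on coercion), so every tree evaluates
to a real number comparable to the slice point.  Division is protected:
``x / 0`` evaluates to 1.0, the standard genetic-programming convention,
which keeps evaluation total on arbitrary inputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from typing import Iterator, Mapping, Union

import numpy as np

__all__ = [
    "Node",
    "RuleTree",
    "RuleError",
    "OPERATORS",
    "DEFAULT_MAX_GENES",
    "DEFAULT_MAX_DEPTH",
    "evaluate_rule",
    "classify",
    "classify_scores",
    "serialize_rule",
    "parse_rule",
    "count_genes",
    "tree_depth",
    "HOUSEKEEPING_GENES",
    "PUBLISHED_RULE_GENES",
    "PUBLISHED_SLICE_POINT",
    "PUBLISHED_SCORE_RANGE",
    "KEY_GENES",
]

SCHEMA_VERSION = 1

DEFAULT_MAX_GENES = 7
DEFAULT_MAX_DEPTH = 10

#: The five reference (housekeeping) genes used for Ct normalization.
HOUSEKEEPING_GENES = ("B2M", "GUSB", "POLR2L", "PSMB6", "UBC")

#: Constants of the published 5-gene recurrence rule.  The algebraic form
#: of that rule was never released, so only its gene set, slice point and
#: observed score range are representable here; they are shipped as data,
#: not re-derived.
PUBLISHED_RULE_GENES = frozenset({"BMI1", "ETV6", "H3F3B", "RPS10", "VEGFA"})
PUBLISHED_SLICE_POINT = -4.4777
PUBLISHED_SCORE_RANGE = (-92.8245, 69.7508)

#: The 18 "key genes" retained for final candidate-rule generation, with
#: their reported frequency of use (percent) across candidate rules.
#: Frequencies below 1% are stored as 0.5.
KEY_GENES = {
    "MMP2": 36.0, "AKT1": 23.0, "RPS10": 19.0, "NFKB1": 16.0,
    "CD82": 13.0, "ARHGDIB": 12.0, "H3F3B": 12.0, "BMI1": 11.0,
    "VEGFA": 10.0, "ETV6": 9.0, "HMOX1": 9.0, "ARAF": 6.0,
    "PTK2": 5.0, "DIABLO": 4.0, "MAX": 2.0, "FGFR4": 1.0,
    "ITGB1": 0.5, "MAPK14": 0.5,
}


class RuleError(ValueError):
    """Malformed rule document or constraint violation."""


# operator name -> arity
OPERATORS: dict[str, int] = {
    "add": 2,
    "sub": 2,
    "mul": 2,
    "div": 2,          # protected division
    "min": 2,
    "max": 2,
    "neg": 1,
    "iflt": 4,         # if a < b then c else d
    "and": 2,
    "or": 2,
    "not": 1,
}

ArrayLike = Union[float, np.ndarray]


@dataclass(frozen=True)
class Node:
    """One node of a rule expression tree.

    Exactly one of ``op``, ``gene``, ``const`` is set.
    """

    op: str | None = None
    children: tuple["Node", ...] = ()
    gene: str | None = None
    const: float | None = None

    def __post_init__(self) -> None:
        kinds = sum(x is not None for x in (self.op, self.gene, self.const))
        if kinds != 1:
            raise RuleError("node must be exactly one of operator/gene/constant")
        if self.op is not None:
            if self.op not in OPERATORS:
                raise RuleError(f"unknown operator {self.op!r}")
            if len(self.children) != OPERATORS[self.op]:
                raise RuleError(
                    f"operator {self.op!r} takes {OPERATORS[self.op]} children, "
                    f"got {len(self.children)}"
                )
        elif self.children:
            raise RuleError("terminal nodes take no children")
        if self.const is not None and not math.isfinite(self.const):
            raise RuleError("constants must be finite")

    # -- convenience constructors -------------------------------------
    @staticmethod
    def g(symbol: str) -> "Node":
        return Node(gene=symbol)

    @staticmethod
    def c(value: float) -> "Node":
        return Node(const=float(value))

    @staticmethod
    def call(op: str, *children: "Node") -> "Node":
        return Node(op=op, children=tuple(children))

    def walk(self) -> Iterator["Node"]:
        yield self
        for child in self.children:
            yield from child.walk()


def tree_depth(node: Node) -> int:
    """Depth of a tree; a lone terminal has depth 1."""
    if not node.children:
        return 1
    return 1 + max(tree_depth(c) for c in node.children)


def _gene_set(node: Node) -> set[str]:
    return {n.gene for n in node.walk() if n.gene is not None}


def _truthy(x: ArrayLike) -> ArrayLike:
    return np.asarray(x) > 0


def _eval(node: Node, profile: Mapping[str, ArrayLike]) -> ArrayLike:
    if node.gene is not None:
        try:
            return np.asarray(profile[node.gene], dtype=float)
        except KeyError:
            raise RuleError(f"profile is missing gene {node.gene!r}") from None
    if node.const is not None:
        return node.const
    op = node.op
    ch = node.children
    if op == "add":
        return _eval(ch[0], profile) + _eval(ch[1], profile)
    if op == "sub":
        return _eval(ch[0], profile) - _eval(ch[1], profile)
    if op == "mul":
        return _eval(ch[0], profile) * _eval(ch[1], profile)
    if op == "div":
        num = _eval(ch[0], profile)
        den = _eval(ch[1], profile)
        den = np.asarray(den, dtype=float)
        num = np.asarray(num, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(den == 0.0, 1.0, num / np.where(den == 0.0, 1.0, den))
        return out
    if op == "min":
        return np.minimum(_eval(ch[0], profile), _eval(ch[1], profile))
    if op == "max":
        return np.maximum(_eval(ch[0], profile), _eval(ch[1], profile))
    if op == "neg":
        return -np.asarray(_eval(ch[0], profile), dtype=float)
    if op == "iflt":
        a, b = _eval(ch[0], profile), _eval(ch[1], profile)
        c, d = _eval(ch[2], profile), _eval(ch[3], profile)
        return np.where(np.asarray(a) < np.asarray(b), c, d)
    if op == "and":
        return np.where(_truthy(_eval(ch[0], profile)) & _truthy(_eval(ch[1], profile)), 1.0, 0.0)
    if op == "or":
        return np.where(_truthy(_eval(ch[0], profile)) | _truthy(_eval(ch[1], profile)), 1.0, 0.0)
    if op == "not":
        return np.where(_truthy(_eval(ch[0], profile)), 0.0, 1.0)
    raise RuleError(f"unknown operator {op!r}")  # pragma: no cover


@dataclass
class RuleTree:
    """A classifier rule: expression tree + slice point + risk direction.

    Parameters
    ----------
    root
        Root node of the expression tree.
    slice_point
        The threshold dichotomizing scores.  Scores strictly below the
        slice point form the ``below`` group; scores ``>=`` it form the
        ``at_or_above`` group (the boundary is inclusive on the upper
        side).
    high_risk_side
        Which of the two groups is called *high risk*.  This is data,
        fixed at rule finalization as the side with the higher observed
        recurrence rate, not a convention.
    """

    root: Node
    slice_point: float | None = None
    high_risk_side: str = "at_or_above"
    max_genes: int = DEFAULT_MAX_GENES
    max_depth: int = DEFAULT_MAX_DEPTH

    def __post_init__(self) -> None:
        if self.high_risk_side not in ("below", "at_or_above"):
            raise RuleError(f"invalid high_risk_side {self.high_risk_side!r}")
        n = len(self.genes)
        if n > self.max_genes:
            raise RuleError(f"rule uses {n} distinct genes; limit is {self.max_genes}")
        d = tree_depth(self.root)
        if d > self.max_depth:
            raise RuleError(f"tree depth {d} exceeds limit {self.max_depth}")

    @property
    def genes(self) -> set[str]:
        return _gene_set(self.root)

    @property
    def depth(self) -> int:
        return tree_depth(self.root)

    def with_threshold(self, slice_point: float, high_risk_side: str) -> "RuleTree":
        """Copy of this rule with structure frozen and threshold replaced."""
        return replace(self, slice_point=float(slice_point), high_risk_side=high_risk_side)


def evaluate_rule(rule: RuleTree, profile: Mapping[str, ArrayLike]) -> ArrayLike:
    """Score a profile (or vectorized profiles) with a rule.

    ``profile`` maps gene symbol to a scalar expression value or an
    aligned 1-D array of values (one per sample); the returned score has
    the same shape.  Missing genes raise :class:`RuleError` naming the
    gene.  Division by zero follows the protected convention (-> 1.0),
    so every score is finite.
    """
    out = _eval(rule.root, profile)
    out = np.asarray(out, dtype=float)
    if out.ndim == 0:
        return float(out)
    return out


def score_table(rule: RuleTree, expr: "object") -> "object":
    """Score every row of a samples x genes expression DataFrame.

    Returns a pandas Series indexed like ``expr``.
    """
    import pandas as pd  # local import keeps numpy-only callers light

    missing = rule.genes - set(expr.columns)
    if missing:
        raise RuleError(f"expression table is missing genes: {sorted(missing)}")
    profile = {g: expr[g].to_numpy(dtype=float) for g in rule.genes}
    if not rule.genes:  # constant-only rule
        scores = np.full(len(expr), evaluate_rule(rule, {}))
    else:
        scores = evaluate_rule(rule, profile)
        scores = np.broadcast_to(np.asarray(scores, dtype=float), (len(expr),))
    return pd.Series(scores, index=expr.index, name="score")


def classify(score: float, rule: RuleTree) -> str:
    """Map a score to ``"high"`` or ``"low"`` risk.

    Membership is strict-less versus at-or-above the slice point; there
    is no intermediate class and no gradation within a group.
    """
    if rule.slice_point is None:
        raise RuleError("rule has no slice point; finalize it first")
    side = "below" if score < rule.slice_point else "at_or_above"
    return "high" if side == rule.high_risk_side else "low"


def classify_scores(scores: np.ndarray, rule: RuleTree) -> np.ndarray:
    """Vectorized :func:`classify`; returns an array of 'high'/'low'."""
    if rule.slice_point is None:
        raise RuleError("rule has no slice point; finalize it first")
    at_or_above = np.asarray(scores, dtype=float) >= rule.slice_point
    high_is_upper = rule.high_risk_side == "at_or_above"
    return np.where(at_or_above == high_is_upper, "high", "low")


def count_genes(rule: RuleTree) -> int:
    """Number of *distinct* gene symbols among the rule's terminals."""
    return len(rule.genes)


# -- serialization ----------------------------------------------------

def _node_to_obj(node: Node) -> dict:
    if node.gene is not None:
        return {"gene": node.gene}
    if node.const is not None:
        return {"const": node.const}
    return {"op": node.op, "children": [_node_to_obj(c) for c in node.children]}


def _node_from_obj(obj: object) -> Node:
    if not isinstance(obj, dict):
        raise RuleError("tree nodes must be JSON objects")
    keys = set(obj) & {"op", "gene", "const"}
    if len(keys) != 1:
        raise RuleError("node must have exactly one of op/gene/const")
    if "gene" in obj:
        if not isinstance(obj["gene"], str) or not obj["gene"]:
            raise RuleError("gene terminal must be a nonempty string")
        return Node(gene=obj["gene"])
    if "const" in obj:
        try:
            return Node(const=float(obj["const"]))
        except (TypeError, ValueError) as exc:
            raise RuleError(f"bad constant: {obj['const']!r}") from exc
    children = obj.get("children", [])
    if not isinstance(children, list):
        raise RuleError("children must be a list")
    return Node(op=obj["op"], children=tuple(_node_from_obj(c) for c in children))


def serialize_rule(rule: RuleTree) -> str:
    """Serialize a rule to its JSON document (schema-versioned)."""
    doc = {
        "version": SCHEMA_VERSION,
        "max_genes": rule.max_genes,
        "max_depth": rule.max_depth,
        "slice_point": rule.slice_point,
        "high_risk_side": rule.high_risk_side,
        "tree": _node_to_obj(rule.root),
    }
    return json.dumps(doc, indent=2)


def parse_rule(text: str) -> RuleTree:
    """Parse a rule JSON document.

    Raises :class:`RuleError` on malformed documents, unknown operators,
    or gene-count/depth violations; ``parse_rule(serialize_rule(r))``
    evaluates identically to ``r`` on every profile.
    """
    if not text or not text.strip():
        raise RuleError("empty rule document")
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise RuleError(f"invalid JSON: {exc}") from exc
    if not isinstance(doc, dict) or "tree" not in doc:
        raise RuleError("rule document must be an object with a 'tree' field")
    if doc.get("version") != SCHEMA_VERSION:
        raise RuleError(f"unsupported schema version {doc.get('version')!r}")
    root = _node_from_obj(doc["tree"])
    sp = doc.get("slice_point")
    return RuleTree(
        root=root,
        slice_point=None if sp is None else float(sp),
        high_risk_side=doc.get("high_risk_side", "at_or_above"),
        max_genes=int(doc.get("max_genes", DEFAULT_MAX_GENES)),
        max_depth=int(doc.get("max_depth", DEFAULT_MAX_DEPTH)),
    )
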