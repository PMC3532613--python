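"""Genetic-programming search for dichotomous expression rules.

Evolves populations of :class:`~oncorule.rules.RuleTree` expression
trees against a training expression table, using cross-validated AUC as
fitness.  The search mirrors a multi-run campaign design: several
*sets* of runs, each set constraining the maximum number of distinct
genes a rule may use, with a fixed number of independent runs per set;
every run returns its best rule, and the pooled candidates feed the
downstream gene-frequency analysis and best-rule selection.

Fitness of a rule is the mean AUC over the held-out folds of a
stratified k-fold partition of the training samples: the rule's scores
are computed once and, for each fold, the AUC is taken over that fold's
samples only, so fitness is never measured on a fold's complement.
The slice point plays no role during evolution (AUC is threshold-free);
thresholds are fixed later during rule finalization.

Standard tree-GP machinery: ramped half-and-half initialization,
tournament selection, subtree crossover, subtree/point mutation, and
one elite carried per generation.  The gene-count and depth constraints
are hard: offspring violating them are re-tried and, past a retry cap,
replaced by a copy of a parent.  Runs derive independent seeds from the
campaign seed, so results are reproducible and order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .rules import OPERATORS, Node, RuleTree, tree_depth

__all__ = [
    "EvolutionConfig",
    "CandidateRule",
    "CandidateRuleSet",
    "auc",
    "stratified_folds",
    "cv_fitness",
    "evolve",
]

# Operators offered to the evolutionary search.  The boolean trio is in
# the grammar but degenerate on strictly positive expression values
# (everything is truthy), so it is excluded from the default search set.
DEFAULT_SEARCH_OPERATORS = ("add", "sub", "mul", "div", "min", "max", "neg", "iflt")


@dataclass
class EvolutionConfig:
    """Hyperparameters for one evolution campaign."""

    population_size: int = 200
    n_generations: int = 25
    crossover_prob: float = 0.8
    mutation_prob: float = 0.15
    tournament_size: int = 3
    max_genes: int = 7
    max_depth: int = 6
    n_folds: int = 4
    n_runs_per_set: int = 300
    sets: tuple[int, ...] = (4, 5, 6, 7)   # per-set max_genes caps
    constant_range: tuple[float, float] = (-10.0, 10.0)
    constant_prob: float = 0.2             # chance a terminal is a constant
    operators: tuple[str, ...] = DEFAULT_SEARCH_OPERATORS
    folds_as_runs: bool = False            # alternative campaign reading
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        for name in ("crossover_prob", "mutation_prob", "constant_prob"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_generations < 1 or self.n_runs_per_set < 1:
            raise ValueError("n_generations and n_runs_per_set must be >= 1")
        if self.tournament_size < 1:
            raise ValueError("tournament_size must be >= 1")
        unknown = set(self.operators) - set(OPERATORS)
        if unknown:
            raise ValueError(f"unknown operators: {sorted(unknown)}")
        if not self.sets:
            raise ValueError("need at least one set")


@dataclass(frozen=True)
class CandidateRule:
    rule: RuleTree
    cv_auc: float
    run_id: int
    set_id: int
    fold_id: int | None = None


@dataclass
class CandidateRuleSet:
    """Best-of-run rules from a campaign, with their CV fitness."""

    rules: list[CandidateRule]
    config: EvolutionConfig | None = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.rules)

    def __iter__(self):
        return iter(self.rules)


def auc(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """Rank-based AUC (ties count one-half).

    Equals the Mann-Whitney U statistic divided by n1*n0; requires both
    classes present.
    """
    y = np.asarray(labels, dtype=bool)
    s = np.asarray(scores, dtype=float)
    if s.shape != y.shape:
        raise ValueError("scores and labels must align")
    n1 = int(y.sum())
    n0 = y.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(s)  # average ranks handle ties as half-wins
    u = ranks[y].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def stratified_folds(labels: Sequence[bool], k: int, seed: int | np.random.Generator) -> np.ndarray:
    """Assign samples to k folds, stratified by class.

    Per class, fold sizes differ by at most one.  Deterministic for a
    fixed seed.  Raises if either class has fewer than k members or if
    k < 2 (no held-out data otherwise).
    """
    y = np.asarray(labels, dtype=bool)
    if k < 2:
        raise ValueError("k must be >= 2 to hold data out")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    folds = np.empty(y.size, dtype=int)
    for cls in (True, False):
        idx = np.flatnonzero(y == cls)
        if idx.size < k:
            raise ValueError(f"class {cls} has {idx.size} members; need >= {k}")
        perm = rng.permutation(idx)
        folds[perm] = np.arange(perm.size) % k
    return folds


def cv_fitness(
    rule: RuleTree,
    table: "pd.DataFrame | dict[str, np.ndarray]",
    labels: Sequence[bool],
    folds: np.ndarray,
) -> float:
    """Mean held-out AUC of a rule across folds.

    Scores are computed once; for each fold the AUC is evaluated on
    that fold's samples only.  A fold containing a single class is
    skipped (and does not contribute); if every fold is degenerate the
    fitness is 0.5.
    """
    if isinstance(table, pd.DataFrame):
        profile = {g: table[g].to_numpy(dtype=float) for g in rule.genes}
        n = len(table)
    else:
        profile = table
        n = len(next(iter(table.values()))) if table else len(labels)
    y = np.asarray(labels, dtype=bool)
    scores = _scores_vector(rule, profile, n)
    folds = np.asarray(folds)
    aucs = []
    for f in np.unique(folds):
        mask = folds == f
        yf = y[mask]
        if yf.all() or not yf.any():
            continue  # degenerate fold: skipped
        aucs.append(auc(scores[mask], yf))
    if not aucs:
        return 0.5
    return float(np.mean(aucs))


def _scores_vector(rule: RuleTree, profile: dict[str, np.ndarray], n: int) -> np.ndarray:
    from .rules import evaluate_rule

    s = evaluate_rule(rule, profile)
    return np.broadcast_to(np.asarray(s, dtype=float), (n,)).copy()


# ---------------------------------------------------------------------
# tree construction and variation


def _random_terminal(rng: np.random.Generator, genes: list[str], cfg: EvolutionConfig) -> Node:
    if rng.random() < cfg.constant_prob:
        lo, hi = cfg.constant_range
        return Node.c(float(rng.uniform(lo, hi)))
    return Node.g(genes[rng.integers(len(genes))])


def _random_tree(
    rng: np.random.Generator,
    genes: list[str],
    cfg: EvolutionConfig,
    depth: int,
    full: bool,
) -> Node:
    if depth <= 1 or (not full and depth < cfg.max_depth and rng.random() < 0.3):
        return _random_terminal(rng, genes, cfg)
    op = cfg.operators[rng.integers(len(cfg.operators))]
    children = tuple(
        _random_tree(rng, genes, cfg, depth - 1, full) for _ in range(OPERATORS[op])
    )
    return Node(op=op, children=children)


def _constrained_tree(
    rng: np.random.Generator, genes: list[str], cfg: EvolutionConfig,
    depth: int, full: bool, max_genes: int, tries: int = 20,
) -> Node:
    for _ in range(tries):
        t = _random_tree(rng, genes, cfg, depth, full)
        if len({n.gene for n in t.walk() if n.gene}) <= max_genes:
            return t
    # fallback: a minimal two-terminal tree cannot exceed any cap >= 1
    return Node.call("sub", _random_terminal(rng, genes, cfg), _random_terminal(rng, genes, cfg))


def _nodes(tree: Node) -> list[Node]:
    return list(tree.walk())


def _replace_at(tree: Node, target_idx: int, new: Node, counter: list[int]) -> Node:
    """Rebuild ``tree`` with the node at preorder index ``target_idx`` replaced."""
    idx = counter[0]
    counter[0] += 1
    if idx == target_idx:
        return new
    if not tree.children:
        return tree
    children = tuple(
        _replace_at(c, target_idx, new, counter) for c in tree.children
    )
    return Node(op=tree.op, children=children)


def _crossover(
    rng: np.random.Generator, a: Node, b: Node
) -> Node:
    na, nb = _nodes(a), _nodes(b)
    ia = int(rng.integers(len(na)))
    ib = int(rng.integers(len(nb)))
    return _replace_at(a, ia, nb[ib], [0])


def _mutate(
    rng: np.random.Generator, tree: Node, genes: list[str], cfg: EvolutionConfig
) -> Node:
    nodes = _nodes(tree)
    consts = [i for i, n in enumerate(nodes) if n.const is not None]
    if consts and rng.random() < 0.5:
        # gaussian point mutation on a constant
        i = consts[int(rng.integers(len(consts)))]
        lo, hi = cfg.constant_range
        jitter = rng.normal(0.0, 0.1 * (hi - lo))
        return _replace_at(tree, i, Node.c(nodes[i].const + jitter), [0])
    i = int(rng.integers(len(nodes)))
    sub = _random_tree(rng, genes, cfg, depth=3, full=False)
    return _replace_at(tree, i, sub, [0])


def _ok(tree: Node, max_genes: int, max_depth: int) -> bool:
    if tree_depth(tree) > max_depth:
        return False
    return len({n.gene for n in tree.walk() if n.gene}) <= max_genes


# ---------------------------------------------------------------------


def _single_run(
    profile: dict[str, np.ndarray],
    y: np.ndarray,
    genes: list[str],
    cfg: EvolutionConfig,
    max_genes: int,
    rng: np.random.Generator,
) -> tuple[RuleTree, float]:
    """One independent GP search; returns the best rule and its fitness."""
    n = y.size
    folds = stratified_folds(y, cfg.n_folds, rng)

    def fitness(tree: Node) -> float:
        rule = RuleTree(root=tree, max_genes=max_genes, max_depth=cfg.max_depth)
        return cv_fitness(rule, profile, y, folds)

    # ramped half-and-half initialization
    pop: list[Node] = []
    depths = list(range(2, max(3, cfg.max_depth // 2 + 2)))
    for i in range(cfg.population_size):
        d = depths[i % len(depths)]
        pop.append(_constrained_tree(rng, genes, cfg, d, full=(i % 2 == 0), max_genes=max_genes))
    fits = np.array([fitness(t) for t in pop])

    best_i = int(np.argmax(fits))
    best_tree, best_fit = pop[best_i], float(fits[best_i])

    for _gen in range(cfg.n_generations):
        new_pop: list[Node] = [best_tree]  # elite
        while len(new_pop) < cfg.population_size:
            p1 = _tournament(rng, pop, fits, cfg.tournament_size)
            child = p1
            if rng.random() < cfg.crossover_prob:
                p2 = _tournament(rng, pop, fits, cfg.tournament_size)
                for _ in range(10):
                    cand = _crossover(rng, p1, p2)
                    if _ok(cand, max_genes, cfg.max_depth):
                        child = cand
                        break
            if rng.random() < cfg.mutation_prob:
                for _ in range(10):
                    cand = _mutate(rng, child, genes, cfg)
                    if _ok(cand, max_genes, cfg.max_depth):
                        child = cand
                        break
            new_pop.append(child)
        pop = new_pop
        fits = np.array([fitness(t) for t in pop])
        gen_best = int(np.argmax(fits))
        if fits[gen_best] > best_fit:
            best_fit = float(fits[gen_best])
            best_tree = pop[gen_best]

    rule = RuleTree(root=best_tree, max_genes=max_genes, max_depth=cfg.max_depth)
    return rule, best_fit


def _tournament(
    rng: np.random.Generator, pop: list[Node], fits: np.ndarray, k: int
) -> Node:
    idx = rng.integers(len(pop), size=k)
    return pop[int(idx[np.argmax(fits[idx])])]


def evolve(
    table: pd.DataFrame,
    labels: Sequence[bool],
    config: EvolutionConfig,
) -> CandidateRuleSet:
    """Run the full multi-set campaign and pool best-of-run rules.

    ``table`` is a samples x genes expression DataFrame; ``labels`` the
    per-sample recurrence outcomes.  Each of ``len(config.sets)`` sets
    runs ``n_runs_per_set`` independent searches (times ``n_folds``
    when ``folds_as_runs`` is set), each capped at that set's
    ``max_genes``; the cross-validation folds are internal to fitness.
    Fully reproducible for a fixed ``config.seed``; per-run seeds are
    derived so runs are independent of execution order.
    """
    from .preprocess import ExpressionTable

    if isinstance(table, ExpressionTable):
        table = table.values
    y = np.asarray(labels, dtype=bool)
    if len(table) != y.size:
        raise ValueError("labels must align with the expression table")
    if y.sum() < 2 or (~y).sum() < 2:
        raise ValueError("need at least 2 samples per class")
    genes = list(table.columns)
    profile = {g: table[g].to_numpy(dtype=float) for g in genes}

    runs_multiplier = config.n_folds if config.folds_as_runs else 1
    out: list[CandidateRule] = []
    for set_id, max_genes in enumerate(config.sets):
        if max_genes < 1:
            raise ValueError("set max_genes must be >= 1")
        for run_id in range(config.n_runs_per_set * runs_multiplier):
            ss = np.random.SeedSequence(
                entropy=config.seed, spawn_key=(set_id, run_id)
            )
            rng = np.random.default_rng(ss)
            rule, fit = _single_run(profile, y, genes, config, max_genes, rng)
            out.append(
                CandidateRule(rule=rule, cv_auc=fit, run_id=run_id, set_id=set_id)
            )
    return CandidateRuleSet(rules=out, config=config)
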