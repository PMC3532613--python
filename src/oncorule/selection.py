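"""Candidate-rule analysis and finalization.

Three post-evolution steps: (1) tabulate how often each gene appears
across the candidate rules (distinct presence per rule), (2) pick the
best rule by AUC on the reserved test set, and (3) refine the winning
rule's slice point on the combined training + test samples, fixing the
high-risk side as the side of the threshold with the higher observed
recurrence rate.  The refinement objective is Youden's J
(sensitivity + specificity - 1), evaluated at every midpoint between
adjacent distinct scores; the rule's structure is frozen before
refinement -- only the threshold and risk direction change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gp import CandidateRule, CandidateRuleSet, auc
from .rules import RuleTree, score_table

__all__ = [
    "gene_use_frequency",
    "select_key_genes",
    "select_best_rule",
    "youden_threshold",
    "refine_slice_point",
    "KeyGeneSelection",
]


def gene_use_frequency(candidates: CandidateRuleSet) -> pd.Series:
    """Percent of candidate rules containing each gene.

    A gene used several times within one rule counts once.  Sorted
    descending (alphabetical within ties), in the layout of a
    frequency-of-gene-use table.
    """
    rules = list(candidates)
    if not rules:
        raise ValueError("empty candidate set")
    counts: dict[str, int] = {}
    for cand in rules:
        for g in cand.rule.genes:
            counts[g] = counts.get(g, 0) + 1
    freq = pd.Series(counts, dtype=float) * 100.0 / len(rules)
    freq = freq.sort_index().sort_values(ascending=False, kind="stable")
    freq.name = "percent"
    freq.index.name = "gene"
    return freq


@dataclass
class KeyGeneSelection:
    genes: list[str]
    table: pd.Series              # percent per selected gene
    tie_at_cutoff: list[str]      # genes tied at the cutoff percent


def select_key_genes(
    freqs: pd.Series,
    top_n: int | None = None,
    min_percent: float | None = None,
) -> KeyGeneSelection:
    """Select the most frequently used genes.

    Either the ``top_n`` genes by frequency (ties at the cutoff broken
    alphabetically and reported) or all genes with frequency >=
    ``min_percent``.  Raises when the criterion selects nothing.
    """
    if (top_n is None) == (min_percent is None):
        raise ValueError("supply exactly one of top_n / min_percent")
    ordered = freqs.sort_index().sort_values(ascending=False, kind="stable")
    if top_n is not None:
        if top_n < 1:
            raise ValueError("top_n must be >= 1")
        chosen = ordered.iloc[: int(top_n)]
        if chosen.empty:
            raise ValueError("criterion selected zero genes")
        # report a tie whenever genes outside the selection share the
        # cutoff frequency with genes inside it
        cutoff = float(chosen.iloc[-1])
        tied = sorted(ordered.index[ordered == cutoff])
        n_at_cut_kept = int((chosen == cutoff).sum())
        tie = tied if len(tied) > n_at_cut_kept else []
        return KeyGeneSelection(genes=list(chosen.index), table=chosen, tie_at_cutoff=tie)
    chosen = ordered[ordered >= float(min_percent)]
    if chosen.empty:
        raise ValueError("criterion selected zero genes")
    return KeyGeneSelection(genes=list(chosen.index), table=chosen, tie_at_cutoff=[])


def select_best_rule(
    candidates: CandidateRuleSet,
    test_table: pd.DataFrame,
    test_labels: "np.ndarray | list[bool]",
) -> tuple[CandidateRule, float]:
    """Pick the candidate with maximal AUC on the reserved test set.

    Ties are broken by fewer distinct genes, then lower tree depth,
    then earliest (set_id, run_id).
    """
    rules = list(candidates)
    if not rules:
        raise ValueError("empty candidate set")
    y = np.asarray(test_labels, dtype=bool)
    scored = []
    for cand in rules:
        s = score_table(cand.rule, test_table).to_numpy()
        scored.append((cand, auc(s, y)))
    best = min(
        scored,
        key=lambda cs: (
            -cs[1],
            len(cs[0].rule.genes),
            cs[0].rule.depth,
            cs[0].set_id,
            cs[0].run_id,
        ),
    )
    return best[0], float(best[1])


@dataclass(frozen=True)
class ThresholdResult:
    threshold: float
    high_risk_side: str
    j: float                      # Youden's J at the threshold
    sensitivity: float
    specificity: float


def youden_threshold(scores: "np.ndarray | list[float]", labels: "np.ndarray | list[bool]") -> ThresholdResult:
    """Threshold maximizing Youden's J over adjacent-score midpoints.

    Candidate cuts are the midpoints between adjacent distinct sorted
    scores.  For each cut both orientations are considered; the winning
    orientation defines the high-risk side (the side with the higher
    recurrence proportion).  J-ties are broken in favor of the cut
    closest to the score median.  All-identical scores raise.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape:
        raise ValueError("scores and labels must align")
    if not y.any() or y.all():
        raise ValueError("both classes must be present")
    distinct = np.unique(s)
    if distinct.size < 2:
        raise ValueError("all scores identical; no threshold exists")
    cuts = (distinct[:-1] + distinct[1:]) / 2.0
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    med = float(np.median(s))

    best: ThresholdResult | None = None
    best_key: tuple[float, float] | None = None
    for t in cuts:
        upper = s >= t
        for side, high_mask in (("at_or_above", upper), ("below", ~upper)):
            sens = float(np.sum(high_mask & y)) / n_pos
            spec = float(np.sum(~high_mask & ~y)) / n_neg
            j = sens + spec - 1.0
            key = (-j, abs(t - med))
            if best_key is None or key < best_key:
                best_key = key
                best = ThresholdResult(
                    threshold=float(t), high_risk_side=side,
                    j=j, sensitivity=sens, specificity=spec,
                )
    assert best is not None
    return best


def refine_slice_point(
    rule: RuleTree,
    combined_table: pd.DataFrame,
    combined_labels: "np.ndarray | list[bool]",
) -> tuple[RuleTree, ThresholdResult]:
    """Finalize a rule's threshold on the combined train + test set.

    The expression structure is frozen; only the slice point and the
    high-risk side are (re)fixed, the latter as the side with the
    higher observed recurrence proportion.  Returns the finalized rule
    and the threshold diagnostics.
    """
    scores = score_table(rule, combined_table).to_numpy()
    res = youden_threshold(scores, combined_labels)
    return rule.with_threshold(res.threshold, res.high_risk_side), res
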