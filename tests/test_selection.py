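"""Gene-frequency analysis, best-rule selection, slice-point refinement."""

import numpy as np
import pandas as pd
import pytest

from oncorule.gp import CandidateRule, CandidateRuleSet, auc
from oncorule.rules import Node, RuleTree, classify_scores, score_table
from oncorule.selection import (
    gene_use_frequency,
    refine_slice_point,
    select_best_rule,
    select_key_genes,
    youden_threshold,
)


def cand(tree, cv_auc=0.5, run_id=0, set_id=0):
    return CandidateRule(rule=RuleTree(root=tree), cv_auc=cv_auc,
                         run_id=run_id, set_id=set_id)


class TestGeneUseFrequency:
    def test_basic_percentages(self):
        rules = [cand(Node.call("sub", Node.g("gA"), Node.g("gB"))) for _ in range(3)]
        rules += [cand(Node.g("gC")) for _ in range(7)]
        freq = gene_use_frequency(CandidateRuleSet(rules=rules))
        assert freq["gA"] == pytest.approx(30.0)
        assert freq["gC"] == pytest.approx(70.0)
        assert "gZ" not in freq  # absent gene simply has no entry

    def test_repeated_use_in_one_rule_counts_once(self):
        tree = Node.call("add", Node.g("gA"), Node.call("mul", Node.g("gA"), Node.g("gA")))
        freq = gene_use_frequency(CandidateRuleSet(rules=[cand(tree)]))
        assert freq["gA"] == pytest.approx(100.0)

    def test_sorted_descending_and_matches_recount(self, rng):
        genes = [f"g{i}" for i in range(8)]
        rules = []
        for _ in range(40):
            chosen = rng.choice(genes, size=rng.integers(1, 4), replace=False)
            tree = Node.g(chosen[0])
            for g in chosen[1:]:
                tree = Node.call("add", tree, Node.g(g))
            rules.append(cand(tree))
        freq = gene_use_frequency(CandidateRuleSet(rules=rules))
        assert list(freq) == sorted(freq, reverse=True)
        for g in freq.index:  # brute-force recount
            expected = 100.0 * sum(g in c.rule.genes for c in rules) / 40
            assert freq[g] == pytest.approx(expected)
        assert ((freq >= 0) & (freq <= 100)).all()

    def test_empty_set_raises(self):
        with pytest.raises(ValueError, match="empty"):
            gene_use_frequency(CandidateRuleSet(rules=[]))


class TestSelectKeyGenes:
    def _freqs(self):
        return pd.Series({"gA": 40.0, "gB": 30.0, "gC": 30.0, "gD": 10.0, "gE": 5.0})

    def test_top_n(self):
        sel = select_key_genes(self._freqs(), top_n=2)
        assert sel.genes == ["gA", "gB"]  # tie gB/gC broken alphabetically
        assert sel.tie_at_cutoff == ["gB", "gC"]

    def test_top_n_without_tie_reports_none(self):
        sel = select_key_genes(self._freqs(), top_n=4)
        assert sel.genes == ["gA", "gB", "gC", "gD"]
        assert sel.tie_at_cutoff == []

    def test_min_percent(self):
        sel = select_key_genes(self._freqs(), min_percent=30.0)
        assert sel.genes == ["gA", "gB", "gC"]

    def test_impossible_criterion_raises(self):
        with pytest.raises(ValueError, match="zero genes"):
            select_key_genes(self._freqs(), min_percent=100.0)

    def test_exactly_one_criterion_required(self):
        with pytest.raises(ValueError):
            select_key_genes(self._freqs())
        with pytest.raises(ValueError):
            select_key_genes(self._freqs(), top_n=2, min_percent=10.0)

    def test_top_18_of_large_table(self, rng):
        freqs = pd.Series(rng.uniform(0, 50, 225),
                          index=[f"g{i:03d}" for i in range(225)])
        sel = select_key_genes(freqs, top_n=18)
        assert len(sel.genes) == 18


class TestSelectBestRule:
    def _table(self, rng, n=30):
        return pd.DataFrame({g: rng.uniform(1, 100, n) for g in ("gA", "gB", "gC")})

    def test_argmax_by_test_auc(self, rng):
        table = self._table(rng)
        labels = rng.random(30) < 0.5
        labels[:3], labels[-3:] = False, True
        # gA made informative
        table.loc[labels, "gA"] += 200
        cands = CandidateRuleSet(rules=[
            cand(Node.g("gB"), run_id=0),
            cand(Node.g("gA"), run_id=1),
            cand(Node.g("gC"), run_id=2),
        ])
        best, best_auc = select_best_rule(cands, table, labels)
        assert best.run_id == 1
        assert best_auc == auc(table["gA"], labels)

    def test_tie_broken_by_fewer_genes(self, rng):
        table = self._table(rng)
        labels = np.array([False] * 15 + [True] * 15)
        table.loc[labels, "gA"] = rng.uniform(60, 80, 15)
        table.loc[~labels, "gA"] = rng.uniform(1, 20, 15)
        # both rules use gA monotonically -> identical AUC = 1
        five = Node.call("add", Node.g("gA"),
                         Node.call("mul", Node.c(0.0),
                                   Node.call("add", Node.g("gB"), Node.g("gC"))))
        cands = CandidateRuleSet(rules=[cand(five, run_id=0), cand(Node.g("gA"), run_id=1)])
        best, _ = select_best_rule(cands, table, labels)
        assert best.run_id == 1

    def test_matches_exhaustive_oracle(self, rng):
        from oncorule.gp import _constrained_tree, EvolutionConfig

        table = self._table(rng, n=40)
        labels = rng.random(40) < 0.5
        labels[:2], labels[-2:] = False, True
        cfg = EvolutionConfig(seed=0)
        cands = CandidateRuleSet(rules=[
            cand(_constrained_tree(rng, list(table.columns), cfg, 3, False, 3), run_id=i)
            for i in range(50)
        ])
        _, best_auc = select_best_rule(cands, table, labels)
        oracle = max(auc(score_table(c.rule, table).to_numpy(), labels) for c in cands)
        assert best_auc == pytest.approx(oracle, abs=1e-12)

    def test_empty_candidates_raise(self, rng):
        with pytest.raises(ValueError):
            select_best_rule(CandidateRuleSet(rules=[]), self._table(rng), [True, False])


class TestYoudenThreshold:
    def test_four_point_example(self):
        res = youden_threshold([-10.0, -5.0, 0.0, 5.0], [False, False, True, True])
        assert res.threshold == pytest.approx(-2.5)
        assert res.high_risk_side == "at_or_above"
        assert res.j == pytest.approx(1.0)

    def test_perfect_separation_reproduces_labels(self, rng):
        scores = np.concatenate([rng.uniform(-10, -1, 20), rng.uniform(1, 10, 30)])
        labels = np.array([False] * 20 + [True] * 30)
        res = youden_threshold(scores, labels)
        assert res.sensitivity == 1.0 and res.specificity == 1.0
        rule = RuleTree(root=Node.g("g"), slice_point=res.threshold,
                        high_risk_side=res.high_risk_side)
        calls = classify_scores(scores, rule)
        assert (calls == np.where(labels, "high", "low")).all()

    def test_inverted_labels_flip_side_same_j(self, rng):
        scores = rng.normal(size=60)
        labels = scores + rng.normal(0, 0.5, 60) > 0
        a = youden_threshold(scores, labels)
        b = youden_threshold(scores, ~labels)
        assert a.j == pytest.approx(b.j)
        assert {a.high_risk_side, b.high_risk_side} == {"below", "at_or_above"}

    def test_identical_scores_raise(self):
        with pytest.raises(ValueError, match="identical"):
            youden_threshold([1.0, 1.0, 1.0], [True, False, True])

    def test_beats_dense_grid_oracle(self, rng):
        """J at the chosen cut >= J of every threshold on a dense grid,
        for 100 random score sets."""
        for _ in range(100):
            n = int(rng.integers(8, 60))
            scores = np.round(rng.normal(size=n), rng.integers(0, 3))
            labels = rng.random(n) < rng.uniform(0.2, 0.8)
            if labels.all() or not labels.any() or np.unique(scores).size < 2:
                continue
            res = youden_threshold(scores, labels)
            grid = np.linspace(scores.min() - 1, scores.max() + 1, 400)
            n_pos, n_neg = labels.sum(), (~labels).sum()
            for t in grid:
                for mask in (scores >= t, scores < t):
                    j = (mask & labels).sum() / n_pos + (~mask & ~labels).sum() / n_neg - 1
                    assert res.j >= j - 1e-12


class TestRefineSlicePoint:
    def test_structure_frozen_only_threshold_changes(self, small_cohort):
        from oncorule.preprocess import normalize_expression
        from oncorule.rules import serialize_rule
        import json

        cfg, panel, clinical = small_cohort
        expr = normalize_expression(panel).values
        labels = clinical["recurred_36mo"].to_numpy(dtype=bool)
        final, res = refine_slice_point(cfg.planted_rule, expr, labels)
        a = json.loads(serialize_rule(cfg.planted_rule))["tree"]
        b = json.loads(serialize_rule(final))["tree"]
        assert a == b
        assert final.slice_point == pytest.approx(res.threshold)

    def test_end_to_end_recovery_on_fresh_cohort(self):
        """Planted 2-gene rule, slice refined on one cohort, applied to a
        fresh cohort: sensitivity and specificity both >= 0.8 (n=500)."""
        from conftest import planted_ratio_rule
        from oncorule.diagnostics import ConfusionCounts
        from oncorule.preprocess import normalize_expression
        from oncorule.synthetic import CohortConfig, generate_cohort

        cfg = CohortConfig(n_patients=500, n_target_genes=15,
                           planted_rule=planted_ratio_rule(), seed=41)
        panel, clinical = generate_cohort(cfg)
        expr = normalize_expression(panel).values
        labels = clinical["recurred_36mo"].to_numpy(dtype=bool)
        final, _ = refine_slice_point(cfg.planted_rule, expr, labels)

        vcfg = CohortConfig(n_patients=500, n_target_genes=15,
                            planted_rule=planted_ratio_rule(), seed=42)
        vpanel, vclinical = generate_cohort(vcfg)
        vexpr = normalize_expression(vpanel).values
        calls = classify_scores(score_table(final, vexpr).to_numpy(), final)
        counts = ConfusionCounts.from_calls(calls, vclinical["recurred_36mo"].to_numpy(dtype=bool))
        assert counts.tp / (counts.tp + counts.fn) >= 0.8
        assert counts.tn / (counts.tn + counts.fp) >= 0.8
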