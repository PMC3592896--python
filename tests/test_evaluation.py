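"""Hold-out splitting, ROC/AUROC, and confusion statistics against
rank-based and exact-combinatorics oracles."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest

from ipfddi import (
    build_network,
    candidate_universe,
    confusion_report,
    expected_overlap,
    expected_random_hits,
    holdout_split,
    roc_from_scores,
    roc_holdout,
)
from ipfddi.network import ValidationError

from conftest import random_network


def mann_whitney_auroc(pos, neg):
    """Brute-force pairwise-comparison AUROC with half credit for ties."""
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def hypergeom_upper_tail(tp, universe, positives, draws):
    """Exact rational P[X >= tp] for X ~ Hypergeom(universe, positives, draws)."""
    total = Fraction(0)
    denom = math.comb(universe, draws)
    for k in range(tp, min(draws, positives) + 1):
        total += Fraction(math.comb(positives, k) * math.comb(universe - positives, draws - k), denom)
    return float(total)


class TestHoldoutSplit:
    def test_size_round_half_even_on_9454_edges(self):
        # complete-graph prefix with exactly 9,454 edges
        ids = [f"d{i:03d}" for i in range(140)]
        edges = list(itertools.combinations(ids, 2))[:9454]
        net = build_network(edges)
        split = holdout_split(net, 0.15, seed=7)
        assert len(split.held_out) == 1418
        assert split.train.n_edges == 9454 - 1418

    def test_ten_edges_thirty_percent(self, rng):
        ids = [f"d{i}" for i in range(20)]
        edges = [(ids[2 * i], ids[2 * i + 1], "") for i in range(10)]
        net = build_network(edges)
        split = holdout_split(net, 0.30, seed=3)
        assert len(split.held_out) == 3

    def test_seed_determinism_and_partition(self, rng):
        net = random_network(rng, 25)
        s1 = holdout_split(net, 0.2, seed=11)
        s2 = holdout_split(net, 0.2, seed=11)
        assert s1.held_out == s2.held_out
        train_pairs = {(a, b) for a, b, _ in s1.train.edges()}
        all_pairs = {(a, b) for a, b, _ in net.edges()}
        assert set(s1.held_out) | train_pairs == all_pairs
        assert not set(s1.held_out) & train_pairs
        # drugs never removed, symmetry preserved
        assert s1.train.index == net.index
        assert np.array_equal(s1.train.adjacency, s1.train.adjacency.T)

    def test_fraction_bounds(self, rng):
        net = random_network(rng, 10)
        for bad in (0.0, 1.0, -0.1, 1.5):
            with pytest.raises(ValidationError):
                holdout_split(net, bad, seed=0)


class TestRoc:
    def test_perfect_separation(self):
        roc = roc_from_scores(np.ones(10), np.zeros(50))
        assert roc.auroc == 1.0

    def test_all_tied_gives_half(self):
        roc = roc_from_scores(np.full(7, 0.3), np.full(13, 0.3))
        assert roc.auroc == pytest.approx(0.5)

    def test_points_monotone_from_origin_to_corner(self, rng):
        roc = roc_from_scores(rng.random(40), rng.random(60))
        fpr = [p[0] for p in roc.points]
        tpr = [p[1] for p in roc.points]
        assert fpr[0] == 0.0 and tpr[0] == 0.0
        assert fpr[-1] == 1.0 and tpr[-1] == 1.0
        assert all(a <= b for a, b in zip(fpr, fpr[1:]))
        assert all(a <= b for a, b in zip(tpr, tpr[1:]))

    def test_sweep_equals_mann_whitney_with_ties(self, rng):
        for _ in range(10):
            # coarse grid of scores forces heavy ties
            pos = rng.integers(0, 8, size=int(rng.integers(5, 60))) / 7.0
            neg = rng.integers(0, 8, size=int(rng.integers(5, 120))) / 7.0
            roc = roc_from_scores(pos, neg)
            assert roc.auroc == pytest.approx(mann_whitney_auroc(pos, neg), abs=1e-12)

    def test_sweep_matches_sklearn_cross_check(self, rng):
        from sklearn.metrics import roc_auc_score

        pos, neg = rng.random(50), rng.random(80)
        roc = roc_from_scores(pos, neg)
        y = np.concatenate([np.ones(50), np.zeros(80)])
        s = np.concatenate([pos, neg])
        assert roc.auroc == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_empty_side_rejected(self):
        with pytest.raises(ValidationError):
            roc_from_scores(np.array([]), np.ones(3))
        with pytest.raises(ValidationError):
            roc_from_scores(np.ones(3), np.array([]))


def test_roc_holdout_matches_rank_oracle(rng):
    from ipfddi.evaluation import holdout_scores

    net = random_network(rng, 35, edge_prob=0.2)
    split = holdout_split(net, 0.15, seed=5)
    roc = roc_holdout(split)
    pos, neg = holdout_scores(split)
    n = net.n_drugs
    assert roc.n_pos == len(split.held_out)
    assert roc.n_pos + roc.n_neg + split.train.n_edges == n * (n - 1) // 2
    assert roc.auroc == pytest.approx(mann_whitney_auroc(pos, neg), abs=1e-12)


class TestConfusionReport:
    def test_identities_and_fisher_oracle_small_universe(self):
        preds = [(f"a{i}", f"b{i}") for i in range(30)]
        reference = set(preds[:12])
        rep = confusion_report(preds, reference, universe_pairs=1500, universe_positives=200)
        assert rep.tp == 12 and rep.fp == 18
        assert rep.precision == pytest.approx(12 / 30)
        assert rep.random_precision == pytest.approx(200 / 1500)
        assert rep.enrichment_factor == pytest.approx((12 / 30) / (200 / 1500))
        assert rep.fisher_p == pytest.approx(
            hypergeom_upper_tail(12, 1500, 200, 30), rel=1e-10
        )

    def test_reference_equals_predictions(self):
        preds = [(f"x{i}", f"y{i}") for i in range(10)]
        rep = confusion_report(preds, set(preds), universe_pairs=800, universe_positives=40)
        assert rep.precision == 1.0
        assert rep.fisher_p == pytest.approx(hypergeom_upper_tail(10, 800, 40, 10), rel=1e-10)

    def test_unordered_pair_matching(self):
        rep = confusion_report([("b", "a")], {("a", "b")}, 100, 10)
        assert rep.tp == 1

    def test_training_edge_rejected(self, rng):
        net = random_network(rng, 10, edge_prob=0.5)
        a, b, _ = net.edges()[0]
        with pytest.raises(ValidationError):
            confusion_report([(a, b)], set(), 100, 10, train_network=net)

    def test_empty_predictions_rejected(self):
        with pytest.raises(ValidationError):
            confusion_report([], set(), 100, 10)


class TestClosedFormBaselines:
    def test_candidate_universe_values(self):
        assert candidate_universe(928, 928) == 430_128
        assert candidate_universe(928, 41) == 37_187
        assert candidate_universe(3, 1) == 2

    def test_candidate_universe_matches_enumeration(self):
        for n, f in [(6, 2), (7, 7), (10, 4)]:
            drugs = range(n)
            focal = set(range(f))
            count = sum(
                1 for i, j in itertools.combinations(drugs, 2) if i in focal or j in focal
            )
            assert candidate_universe(n, f) == count
        with pytest.raises(ValidationError):
            candidate_universe(5, 6)

    def test_expected_random_hits(self):
        assert round(expected_random_hits(100, 37187, 7068)) == 19
        assert round(expected_random_hits(100, 37187, 7068) / 100, 2) == 0.19
        assert expected_random_hits(0, 100, 10) == 0.0
        assert expected_random_hits(100, 100, 17) == 17.0

    def test_expected_overlap(self):
        assert round(expected_overlap(3332, 2334, 430128)) == 18
        assert expected_overlap(0, 5, 10) == 0.0
        assert expected_overlap(10, 7, 10) == 7.0
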