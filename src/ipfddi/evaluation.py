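"""Evaluation machinery: hold-out ROC/AUROC, precision, enrichment factor,
and one-sided Fisher exact significance.

Hold-out validation removes a random fraction of known edges, rebuilds the
similarity and prediction matrices from the remainder, and asks how highly
the removed edges score against all remaining non-edges (ROC/AUROC, with the
trapezoidal area equal to the Mann-Whitney statistic under the half-tie
convention).  Test evaluation compares a prediction list against an external
reference standard: precision TP/(TP+FP), the enrichment factor over the
precision of uniform random pair selection from the candidate universe, and
the upper hypergeometric tail as the one-sided Fisher exact p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom

from .network import InteractionNetwork, ValidationError, _pair_key, build_network
from .propagation import PredictionSet, propagate
from .similarity import similarity_matrix


@dataclass
class HoldoutSplit:
    """Edge partition into a training network and held-out positive pairs."""

    train: InteractionNetwork
    held_out: list[tuple[str, str]]
    fraction: float
    seed: int


@dataclass
class RocResult:
    """ROC sweep points (FPR, TPR) and the trapezoidal AUROC."""

    points: list[tuple[float, float]]
    auroc: float
    n_pos: int
    n_neg: int


@dataclass
class ConfusionReport:
    tp: int
    fp: int
    precision: float
    random_precision: float
    enrichment_factor: float
    fisher_p: float
    universe_pairs: int
    universe_positives: int

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "precision": self.precision,
            "random_precision": self.random_precision,
            "enrichment_factor": self.enrichment_factor,
            "fisher_p": self.fisher_p,
            "universe_pairs": self.universe_pairs,
            "universe_positives": self.universe_positives,
        }


def holdout_split(
    network: InteractionNetwork, fraction: float, seed: int
) -> HoldoutSplit:
    """Move a uniformly random ``fraction`` of edges to a held-out test set.

    The held-out size is round(fraction * edge_count) (round half to even).
    Drugs are never removed: the training network keeps the full drug
    universe, only the sampled edges are deleted.  Reproducible by seed.
    """
    if not 0.0 < fraction < 1.0:
        raise ValidationError("hold-out fraction must be in (0, 1)")
    edges = network.edges()
    m = len(edges)
    if m < 2:
        raise ValidationError("need at least 2 edges to split")
    k = round(fraction * m)
    rng = np.random.default_rng(seed)
    held_idx = set(rng.choice(m, size=k, replace=False).tolist())
    train_edges = [e for t, e in enumerate(edges) if t not in held_idx]
    held_out = [(edges[t][0], edges[t][1]) for t in sorted(held_idx)]
    train = build_network(train_edges, extra_drugs=network.index.drug_ids)
    return HoldoutSplit(train=train, held_out=held_out, fraction=fraction, seed=seed)


def roc_from_scores(pos_scores: np.ndarray, neg_scores: np.ndarray) -> RocResult:
    """ROC by descending-score sweep over the pooled unique thresholds.

    Tied positive/negative scores fall at the same threshold, so the curve
    cuts the tie block diagonally and the trapezoidal area equals the
    Mann-Whitney rank statistic with ties counted one half.
    """
    pos = np.asarray(pos_scores, dtype=np.float64)
    neg = np.asarray(neg_scores, dtype=np.float64)
    n_pos, n_neg = pos.size, neg.size
    if n_pos == 0:
        raise ValidationError("no positive pairs to evaluate")
    if n_neg == 0:
        raise ValidationError("no negative pairs to evaluate")
    thresholds = np.unique(np.concatenate([pos, neg]))[::-1]
    # counts of scores >= each threshold
    tp = n_pos - np.searchsorted(np.sort(pos), thresholds, side="left")
    fp = n_neg - np.searchsorted(np.sort(neg), thresholds, side="left")
    tpr = np.concatenate([[0.0], tp / n_pos, [1.0]])
    fpr = np.concatenate([[0.0], fp / n_neg, [1.0]])
    auroc = float(np.trapezoid(tpr, fpr))
    points = list(zip(fpr.tolist(), tpr.tolist()))
    return RocResult(points=points, auroc=auroc, n_pos=n_pos, n_neg=n_neg)


def holdout_scores(split: HoldoutSplit) -> tuple[np.ndarray, np.ndarray]:
    """Propagation scores of held-out pairs (positives) and of all pairs that
    are edges of neither the training nor the held-out set (negatives).

    The model (M2 and M3) is rebuilt from the training network only; a pair
    absent from the propagated set scores 0.
    """
    train = split.train
    m2 = similarity_matrix(train)
    ps = propagate(train, m2)
    n = train.n_drugs
    final = np.zeros((n, n), dtype=np.float64)
    idx = train.index
    for p in ps.predictions:
        i, j = idx[p.drug_a], idx[p.drug_b]
        final[i, j] = final[j, i] = p.score
    pos_mask = np.zeros((n, n), dtype=bool)
    for a, b in split.held_out:
        i, j = idx[a], idx[b]
        pos_mask[i, j] = pos_mask[j, i] = True
    neg_mask = ~(train.adjacency | pos_mask)
    np.fill_diagonal(neg_mask, False)
    iu, ju = np.triu_indices(n, k=1)
    upper_pos = pos_mask[iu, ju]
    upper_neg = neg_mask[iu, ju]
    return final[iu, ju][upper_pos], final[iu, ju][upper_neg]


def roc_holdout(split: HoldoutSplit) -> RocResult:
    """Hold-out ROC: rebuild the model from the training edges and rank the
    held-out pairs against all non-edges."""
    pos, neg = holdout_scores(split)
    return roc_from_scores(pos, neg)


def confusion_report(
    predictions: PredictionSet | list[tuple[str, str]],
    reference: set[tuple[str, str]],
    universe_pairs: int,
    universe_positives: int,
    train_network: InteractionNetwork | None = None,
) -> ConfusionReport:
    """Score a prediction list against a reference standard of positive pairs.

    TP is the number of predicted pairs present in the reference (unordered),
    FP the rest.  ``random_precision`` is universe_positives/universe_pairs —
    the precision of drawing the same number of pairs uniformly from the
    candidate universe; the enrichment factor is precision relative to that.
    ``fisher_p`` is the one-sided (enrichment direction) Fisher exact test:
    the upper hypergeometric tail P[X >= TP] for TP+FP draws from a
    population of universe_pairs containing universe_positives successes.
    """
    if isinstance(predictions, PredictionSet):
        pairs = [p.pair for p in predictions.predictions]
    else:
        pairs = [_pair_key(a, b) for a, b in predictions]
    if len(pairs) == 0:
        raise ValidationError("empty prediction list")
    if universe_positives > universe_pairs:
        raise ValidationError("more positives than pairs in the universe")
    if train_network is not None:
        for a, b in pairs:
            if train_network.has_edge(a, b):
                raise ValidationError(
                    f"prediction ({a}, {b}) is a training edge; evaluate novel pairs only"
                )
    ref = {_pair_key(a, b) for a, b in reference}
    tp = sum(1 for p in pairs if p in ref)
    fp = len(pairs) - tp
    precision = tp / (tp + fp)
    random_precision = universe_positives / universe_pairs
    enrichment_factor = precision / random_precision if random_precision > 0 else np.inf
    fisher_p = float(hypergeom.sf(tp - 1, universe_pairs, universe_positives, tp + fp))
    return ConfusionReport(
        tp=tp,
        fp=fp,
        precision=precision,
        random_precision=random_precision,
        enrichment_factor=enrichment_factor,
        fisher_p=fisher_p,
        universe_pairs=universe_pairs,
        universe_positives=universe_positives,
    )


def candidate_universe(n_drugs: int, focal_drugs: int) -> int:
    """Unordered non-self pairs touching at least one of ``focal_drugs``
    within a universe of ``n_drugs``: f*(n-1) - C(f, 2)."""
    if not 1 <= focal_drugs <= n_drugs:
        raise ValidationError("need 1 <= focal_drugs <= n_drugs")
    return focal_drugs * (n_drugs - 1) - focal_drugs * (focal_drugs - 1) // 2


def expected_random_hits(draws: int, universe_pairs: int, universe_positives: int) -> float:
    """Hypergeometric mean: expected positives among ``draws`` uniform picks."""
    if draws > universe_pairs:
        raise ValidationError("cannot draw more pairs than the universe holds")
    return draws * universe_positives / universe_pairs


def expected_overlap(set1: int, set2: int, universe: int) -> float:
    """Expected size of the intersection of two uniform random subsets of the
    given sizes: set1 * set2 / universe."""
    if set1 > universe or set2 > universe:
        raise ValidationError("set size exceeds universe")
    return set1 * set2 / universe
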