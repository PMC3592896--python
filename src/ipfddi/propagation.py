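"""Max-product propagation of known interactions through profile similarity.

The prediction matrix M3 scores each drug pair {i, j} by the best similarity
route that links them: the directed score S[i][j] is the maximum over known
partners k of drug i of the fingerprint similarity TC(k, j); the final score
of the unordered pair is the larger of the two directions.  Each prediction
records its provenance — the known interaction (anchor, neighbor) that
produced the maximal score — and inherits that interaction's effect text.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .network import InteractionNetwork, ValidationError, _pair_key
from .similarity import SimilarityMatrix


@dataclass(frozen=True)
class Prediction:
    """One scored drug pair with provenance and inherited effect.

    ``source_pair`` is the known interaction (anchor_drug, neighbor_drug)
    whose neighbor's fingerprint matched the other member of the pair;
    ``similar_to`` is that neighbor; ``effect`` is the effect text of the
    source interaction; ``is_known`` marks pairs already present in M1.
    """

    drug_a: str
    drug_b: str
    score: float
    source_pair: tuple[str, str]
    similar_to: str
    effect: str
    is_known: bool

    @property
    def pair(self) -> tuple[str, str]:
        return (self.drug_a, self.drug_b)


@dataclass
class PredictionSet:
    """Collection of predictions, at most one per unordered pair."""

    index: "object"  # DrugIndex
    predictions: list[Prediction]

    def __len__(self) -> int:
        return len(self.predictions)

    def __iter__(self):
        return iter(self.predictions)

    def as_dict(self) -> dict[tuple[str, str], Prediction]:
        return {p.pair: p for p in self.predictions}


def score_matrix(
    m1: InteractionNetwork, m2: SimilarityMatrix
) -> tuple[np.ndarray, np.ndarray]:
    """Directed propagation scores and maximizing neighbors.

    Returns (S, K): S[i, j] = max over known partners k of drug i of
    m2[k, j] (0.0 if drug i is isolated); K[i, j] = the maximizing k,
    smallest index on ties, -1 where there is no partner.  Because the drug
    index is lexicographic, the smallest index is the lexicographically
    smallest identifier.
    """
    if m1.index != m2.index:
        raise ValidationError("interaction network and similarity matrix use different drug indices")
    n = m1.n_drugs
    S = np.zeros((n, n), dtype=np.float64)
    K = np.full((n, n), -1, dtype=np.int64)
    V = m2.values
    for i in range(n):
        partners = np.nonzero(m1.adjacency[i])[0]
        if partners.size == 0:
            continue
        sub = V[partners]  # (n_partners, n)
        best = sub.argmax(axis=0)  # first (= smallest partner index) on ties
        S[i] = sub[best, np.arange(n)]
        K[i] = partners[best]
    return S, K


def propagate(m1: InteractionNetwork, m2: SimilarityMatrix) -> PredictionSet:
    """Generate the prediction set (matrix M3).

    For each unordered pair the final score is max(S[i][j], S[j][i]);
    zero-score pairs and the diagonal are omitted (absent means score 0).
    Provenance is taken from the winning direction; when both directions tie,
    from the direction whose anchor drug identifier is lexicographically
    smaller.  Known edges of M1 are retained, flagged ``is_known``.
    """
    S, K = score_matrix(m1, m2)
    ids = m1.index.drug_ids
    final = np.maximum(S, S.T)
    iu, ju = np.nonzero(np.triu(final, 1))
    predictions: list[Prediction] = []
    for i, j in zip(iu, ju):
        # ids are index-sorted, so ids[i] < ids[j]: direction i->j has the
        # lexicographically smaller anchor and wins ties
        if S[i, j] >= S[j, i]:
            anchor, k = i, int(K[i, j])
        else:
            anchor, k = j, int(K[j, i])
        anchor_id, k_id = ids[anchor], ids[k]
        predictions.append(
            Prediction(
                drug_a=ids[i],
                drug_b=ids[j],
                score=float(final[i, j]),
                source_pair=(anchor_id, k_id),
                similar_to=k_id,
                effect=m1.effects.get(_pair_key(anchor_id, k_id), ""),
                is_known=bool(m1.adjacency[i, j]),
            )
        )
    return PredictionSet(index=m1.index, predictions=predictions)


def _ranked(predictions: list[Prediction]) -> list[Prediction]:
    return sorted(predictions, key=lambda p: (-p.score, p.drug_a, p.drug_b))


def new_predictions(
    ps: PredictionSet,
    m1: InteractionNetwork | None = None,
    tc_min: float = 0.0,
) -> PredictionSet:
    """Novel predictions only: drops known pairs and scores below ``tc_min``;
    result ordered by descending score, ties broken by identifier pair.

    ``m1``, when given, cross-checks the ``is_known`` flags against the
    network the predictions were propagated from.
    """
    if not 0.0 <= tc_min:
        raise ValidationError("tc_min must be non-negative")
    kept = []
    for p in ps.predictions:
        if m1 is not None and p.is_known != m1.has_edge(p.drug_a, p.drug_b):
            raise ValidationError(f"is_known flag inconsistent for {p.pair}")
        if not p.is_known and p.score >= tc_min:
            kept.append(p)
    return PredictionSet(index=ps.index, predictions=_ranked(kept))


def write_predictions(
    ps: PredictionSet, path: str | Path, decimals: int | None = None
) -> None:
    """Write predictions as TSV sorted by descending score (ties by pair):
    ``drug_a drug_b tc is_known anchor_drug similar_drug effect``.

    ``decimals`` rounds the score column for presentation; None keeps full
    precision.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("drug_a\tdrug_b\ttc\tis_known\tanchor_drug\tsimilar_drug\teffect\n")
        for p in _ranked(ps.predictions):
            tc = repr(p.score) if decimals is None else f"{p.score:.{decimals}f}"
            fh.write(
                f"{p.drug_a}\t{p.drug_b}\t{tc}\t{int(p.is_known)}\t"
                f"{p.source_pair[0]}\t{p.similar_to}\t{p.effect}\n"
            )
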