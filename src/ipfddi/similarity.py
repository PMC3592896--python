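"""Tanimoto similarity between interaction profile fingerprints (matrix M2).

The Tanimoto coefficient (Jaccard index) of two fingerprints A and B is
|A ∩ B| / |A ∪ B|.  The pairwise similarity matrix over all drugs is
symmetric, has a forced zero diagonal (a drug's interaction with itself is
not considered), and all entries lie in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .network import Fingerprint, InteractionNetwork

#: above this many drugs the matrix is assembled in row blocks rather than
#: from a single n-by-n product (identical numerical results)
DENSE_LIMIT = 5_000

_BLOCK_ROWS = 512


@dataclass
class SimilarityMatrix:
    """Symmetric fingerprint-similarity matrix with zero diagonal."""

    index: "object"  # DrugIndex
    values: np.ndarray

    @property
    def n_drugs(self) -> int:
        return len(self.index)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto coefficient of two fingerprints: |A∩B| / |A∪B|.

    Both fingerprints empty returns 0.0 (an isolated drug carries no evidence
    of similarity to anything, itself included).
    """
    na, nb = len(a), len(b)
    if na == 0 or nb == 0:
        return 0.0
    inter = np.intersect1d(a.partners, b.partners, assume_unique=True).size
    union = na + nb - inter
    return inter / union


def _tc_rows(adj: np.ndarray, rows: np.ndarray, deg: np.ndarray, mask_mutual: bool) -> np.ndarray:
    block = adj[rows].astype(np.float64)
    inter = block @ adj.astype(np.float64).T
    union = deg[rows][:, None] + deg[None, :] - inter
    if mask_mutual:
        # drop position j from fp(i) and position i from fp(j) when i-j is
        # itself an edge; neither position can be in the intersection
        union = union - 2.0 * adj[rows]
    with np.errstate(invalid="ignore", divide="ignore"):
        tc = np.where(union > 0, inter / np.maximum(union, 1e-300), 0.0)
    return tc


def similarity_matrix(
    network: InteractionNetwork, mask_mutual: bool = False
) -> SimilarityMatrix:
    """All-pairs Tanimoto similarity between interaction fingerprints.

    Parameters
    ----------
    network
        The known-interaction network whose rows are the fingerprints.
    mask_mutual
        When two drugs i and j themselves interact, position j appears in
        fp(i) and position i in fp(j).  By default these positions are kept
        (unmasked sets); with ``mask_mutual`` they are removed from the union
        before the ratio is taken.
    """
    n = network.n_drugs
    adj = network.adjacency
    deg = adj.sum(axis=1).astype(np.float64)
    if n <= DENSE_LIMIT:
        values = _tc_rows(adj, np.arange(n), deg, mask_mutual)
    else:
        values = np.empty((n, n), dtype=np.float64)
        for start in range(0, n, _BLOCK_ROWS):
            rows = np.arange(start, min(start + _BLOCK_ROWS, n))
            values[rows] = _tc_rows(adj, rows, deg, mask_mutual)
    np.fill_diagonal(values, 0.0)
    return SimilarityMatrix(index=network.index, values=values)


def write_similarity(
    sm: SimilarityMatrix, path: str | Path, threshold: float = 0.0
) -> int:
    """Export pairs with TC >= threshold as long-format TSV
    ``drug_a<TAB>drug_b<TAB>tc`` (drug_a < drug_b, sorted); returns the
    number of rows written."""
    ids = sm.index.drug_ids
    iu, ju = np.triu_indices(sm.values.shape[0], k=1)
    keep = sm.values[iu, ju] >= threshold
    rows = sorted(
        (ids[i], ids[j], sm.values[i, j]) for i, j in zip(iu[keep], ju[keep])
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("drug_a\tdrug_b\ttc\n")
        for a, b, tc in rows:
            fh.write(f"{a}\t{b}\t{tc:.6f}\n")
    return len(rows)
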