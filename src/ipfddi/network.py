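"""Known drug-drug interaction network (matrix M1) and fingerprints.

The established DDI database is a symmetric binary drug-by-drug adjacency
matrix with zero diagonal; each edge may carry free-text describing the
pharmacological effect of the interaction.  A drug's interaction profile
fingerprint is the sparse row of this matrix: the sorted set of partner
indices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

EdgeRecord = tuple[str, str, str]


class ValidationError(ValueError):
    """Raised when input records violate the network contract."""


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a < b else (b, a)


@dataclass(frozen=True)
class DrugIndex:
    """Deterministic (lexicographic) mapping between drug identifiers and
    0-based integer indices."""

    drug_ids: tuple[str, ...]
    position: dict[str, int] = field(repr=False)

    @classmethod
    def from_ids(cls, ids: Iterable[str]) -> "DrugIndex":
        unique = sorted(set(ids))
        for d in unique:
            if not d:
                raise ValidationError("empty drug identifier")
        return cls(tuple(unique), {d: i for i, d in enumerate(unique)})

    def __len__(self) -> int:
        return len(self.drug_ids)

    def __getitem__(self, drug: str) -> int:
        return self.position[drug]

    def __contains__(self, drug: str) -> bool:
        return drug in self.position


@dataclass(frozen=True)
class Fingerprint:
    """Interaction profile fingerprint: sorted partner indices of one drug."""

    owner: int
    partners: np.ndarray  # strictly increasing int array

    def __len__(self) -> int:
        return len(self.partners)

    def as_set(self) -> frozenset[int]:
        return frozenset(int(p) for p in self.partners)


@dataclass
class InteractionNetwork:
    """Symmetric binary interaction matrix with per-edge effect text.

    ``adjacency`` is a dense boolean n-by-n array (zero diagonal); ``effects``
    maps the lexicographically ordered identifier pair of every annotated
    edge to its effect string (possibly empty).
    """

    index: DrugIndex
    adjacency: np.ndarray
    effects: dict[tuple[str, str], str]

    @property
    def n_drugs(self) -> int:
        return len(self.index)

    @property
    def n_edges(self) -> int:
        return int(np.triu(self.adjacency, 1).sum())

    def has_edge(self, a: str, b: str) -> bool:
        return bool(self.adjacency[self.index[a], self.index[b]])

    def effect(self, a: str, b: str) -> str:
        return self.effects.get(_pair_key(a, b), "")

    def edges(self) -> list[tuple[str, str, str]]:
        """All edges as (drug_a, drug_b, effect), drug_a < drug_b, sorted."""
        ids = self.index.drug_ids
        ii, jj = np.nonzero(np.triu(self.adjacency, 1))
        out = []
        for i, j in zip(ii, jj):
            a, b = ids[i], ids[j]
            out.append((a, b, self.effects.get((a, b), "")))
        out.sort()
        return out

    def validate(self) -> None:
        n = self.n_drugs
        if self.adjacency.shape != (n, n):
            raise ValidationError("adjacency shape does not match drug index")
        if np.any(np.diagonal(self.adjacency)):
            raise ValidationError("nonzero diagonal in adjacency")
        if not np.array_equal(self.adjacency, self.adjacency.T):
            raise ValidationError("adjacency not symmetric")
        for a, b in self.effects:
            if not self.has_edge(a, b):
                raise ValidationError(f"effect on non-edge ({a}, {b})")


def build_network(
    edges: Sequence[tuple[str, str] | tuple[str, str, str]],
    extra_drugs: Iterable[str] = (),
) -> InteractionNetwork:
    """Build a symmetric interaction network from pairwise records.

    Identifiers are whitespace-trimmed, case-sensitive opaque strings.
    Duplicate records (in either pair order) collapse to one edge; when
    duplicates carry conflicting effect text the first occurrence wins and a
    warning is logged.  Self-pairs are rejected.  ``extra_drugs`` adds
    isolated drugs to the universe (used by generators and hold-out splits,
    where removing an edge must not remove a drug).

    Raises
    ------
    ValidationError
        On an empty edge list, an empty identifier, or a self-loop.
    """
    if len(edges) == 0 and not extra_drugs:
        raise ValidationError("empty edge list")

    cleaned: list[EdgeRecord] = []
    for rec in edges:
        a = rec[0].strip()
        b = rec[1].strip()
        effect = rec[2] if len(rec) > 2 else ""
        if not a or not b:
            raise ValidationError(f"empty drug identifier in record {rec!r}")
        if a == b:
            raise ValidationError(f"self-interaction record for drug {a!r}")
        cleaned.append((a, b, effect))

    ids: set[str] = {d.strip() for d in extra_drugs}
    for d in ids:
        if not d:
            raise ValidationError("empty drug identifier")
    for a, b, _ in cleaned:
        ids.add(a)
        ids.add(b)
    index = DrugIndex.from_ids(ids)

    n = len(index)
    adjacency = np.zeros((n, n), dtype=bool)
    effects: dict[tuple[str, str], str] = {}
    for a, b, effect in cleaned:
        key = _pair_key(a, b)
        if key in effects:
            if effects[key] != effect:
                logger.warning(
                    "conflicting effect for pair %s-%s; keeping first occurrence",
                    key[0],
                    key[1],
                )
            continue
        effects[key] = effect
        i, j = index[a], index[b]
        adjacency[i, j] = True
        adjacency[j, i] = True
    return InteractionNetwork(index, adjacency, effects)


def fingerprint_of(network: InteractionNetwork, drug: int | str) -> Fingerprint:
    """Interaction profile fingerprint of one drug (sorted partner indices).

    Accepts an integer index or a drug identifier; an isolated drug yields an
    empty fingerprint.
    """
    if isinstance(drug, str):
        drug = network.index[drug]
    n = network.n_drugs
    if not 0 <= drug < n:
        raise IndexError(f"drug index {drug} out of range 0..{n - 1}")
    partners = np.nonzero(network.adjacency[drug])[0]
    return Fingerprint(owner=int(drug), partners=partners)


def read_edges(path: str | Path) -> list[EdgeRecord]:
    """Read a TSV edge list: header ``drug_a<TAB>drug_b<TAB>effect`` (effect
    column optional), UTF-8, ``#``-prefixed comment lines ignored."""
    records: list[EdgeRecord] = []
    with open(path, encoding="utf-8") as fh:
        header_seen = False
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if not header_seen:
                header_seen = True
                if parts[0] == "drug_a":
                    continue
            if len(parts) < 2:
                raise ValidationError(f"{path}:{lineno}: expected at least 2 columns")
            effect = parts[2] if len(parts) > 2 else ""
            records.append((parts[0], parts[1], effect))
    return records


def write_edges(network: InteractionNetwork, path: str | Path) -> None:
    """Write the edge list as TSV, pairs ordered drug_a < drug_b, sorted."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("drug_a\tdrug_b\teffect\n")
        for a, b, effect in network.edges():
            fh.write(f"{a}\t{b}\t{effect}\n")
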