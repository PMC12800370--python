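"""Core in-memory containers shared across the pipeline.

The pipeline moves four kinds of objects between stages: per-protein
structures (Cα traces), undirected weighted graphs (the PPI network and
per-protein residue contact graphs), labeled gene-pair tables, and
fixed-dimension embedding tables keyed by entity ID.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

SL = "SL"
NON_SL = "nonSL"


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Return the gene pair in canonical (lexicographic) order.

    All pair-keyed logic — dedup, negative-sampling disjointness, feature
    concatenation — operates on canonical pairs, which is what makes
    predictions symmetric in the two genes.
    """
    if a == b:
        raise ValueError(f"self-pair {a!r} is not a valid gene pair")
    return (a, b) if a < b else (b, a)


@dataclass(frozen=True)
class ProteinStructure:
    """Cα trace of one protein: sequence plus one coordinate per residue (Å)."""

    protein_id: str
    sequence: str
    ca_coords: np.ndarray  # (L, 3) float64

    def __post_init__(self) -> None:
        coords = np.asarray(self.ca_coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("ca_coords must have shape (L, 3)")
        if coords.shape[0] != len(self.sequence):
            raise ValueError(
                f"sequence length {len(self.sequence)} != number of "
                f"coordinates {coords.shape[0]}"
            )
        if not np.all(np.isfinite(coords)):
            raise ValueError("non-finite Cα coordinate")
        object.__setattr__(self, "ca_coords", coords)

    def __len__(self) -> int:
        return len(self.sequence)


class WeightedGraph:
    """Undirected weighted graph with string node IDs.

    No self-loops; weights strictly positive; each edge stored once but
    queryable in either direction.
    """

    def __init__(self) -> None:
        self._adj: dict[str, dict[str, float]] = {}

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str, float]],
        nodes: Iterable[str] = (),
    ) -> "WeightedGraph":
        g = cls()
        for n in nodes:
            g.add_node(n)
        for u, v, w in edges:
            g.add_edge(u, v, w)
        return g

    def add_node(self, n: str) -> None:
        self._adj.setdefault(n, {})

    def add_edge(self, u: str, v: str, weight: float = 1.0) -> None:
        if u == v:
            raise ValueError(f"self-loop on node {u!r}")
        if not weight > 0:
            raise ValueError(f"edge weight must be > 0, got {weight}")
        self._adj.setdefault(u, {})[v] = float(weight)
        self._adj.setdefault(v, {})[u] = float(weight)

    @property
    def nodes(self) -> list[str]:
        return sorted(self._adj)

    def number_of_nodes(self) -> int:
        return len(self._adj)

    def number_of_edges(self) -> int:
        return sum(len(nbrs) for nbrs in self._adj.values()) // 2

    def edges(self) -> Iterator[tuple[str, str, float]]:
        for u in sorted(self._adj):
            for v, w in sorted(self._adj[u].items()):
                if u < v:
                    yield u, v, w

    def neighbors(self, n: str) -> dict[str, float]:
        return self._adj[n]

    def has_edge(self, u: str, v: str) -> bool:
        return v in self._adj.get(u, {})

    def weight(self, u: str, v: str) -> float:
        return self._adj[u][v]

    def __contains__(self, n: str) -> bool:
        return n in self._adj


@dataclass
class PairTable:
    """Labeled gene pairs in canonical order, no duplicates."""

    pairs: list[tuple[str, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: dict[tuple[str, str], str] = {}
        canon: list[tuple[str, str, str]] = []
        for a, b, label in self.pairs:
            if label not in (SL, NON_SL):
                raise ValueError(f"label must be 'SL' or 'nonSL', got {label!r}")
            key = canonical_pair(a, b)
            if key in seen:
                if seen[key] != label:
                    raise ValueError(
                        f"conflicting labels for pair {key}: "
                        f"{seen[key]!r} vs {label!r}"
                    )
                continue
            seen[key] = label
            canon.append((*key, label))
        self.pairs = canon

    @property
    def positives(self) -> set[tuple[str, str]]:
        return {(a, b) for a, b, lab in self.pairs if lab == SL}

    @property
    def negatives(self) -> set[tuple[str, str]]:
        return {(a, b) for a, b, lab in self.pairs if lab == NON_SL}

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class GeneProteinMap:
    """One-to-one gene → protein mapping (after resolution)."""

    entries: dict[str, str]

    def protein_for(self, gene: str) -> str:
        return self.entries[gene]

    def __contains__(self, gene: str) -> bool:
        return gene in self.entries

    def __len__(self) -> int:
        return len(self.entries)


class EmbeddingTable:
    """Fixed-dimension float vectors keyed by entity ID."""

    def __init__(self, ids: Sequence[str], vectors: np.ndarray) -> None:
        vectors = np.asarray(vectors, dtype=float)
        if vectors.ndim != 2:
            raise ValueError("vectors must be a 2-D array")
        if len(ids) != vectors.shape[0]:
            raise ValueError("number of ids must match number of vectors")
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate entity IDs")
        self.ids = list(ids)
        self.vectors = vectors
        self._index = {i: k for k, i in enumerate(self.ids)}

    @classmethod
    def from_dict(cls, d: Mapping[str, np.ndarray]) -> "EmbeddingTable":
        ids = list(d)
        if not ids:
            return cls([], np.empty((0, 0)))
        dims = {np.asarray(v).shape for v in d.values()}
        if len(dims) > 1:
            raise ValueError(f"ragged vector dimensions: {sorted(dims)}")
        return cls(ids, np.stack([np.asarray(d[i], dtype=float) for i in ids]))

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def __getitem__(self, entity_id: str) -> np.ndarray:
        return self.vectors[self._index[entity_id]]

    def __contains__(self, entity_id: str) -> bool:
        return entity_id in self._index

    def __len__(self) -> int:
        return len(self.ids)

    def subset(self, ids: Sequence[str]) -> "EmbeddingTable":
        return EmbeddingTable(list(ids), np.stack([self[i] for i in ids]))
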