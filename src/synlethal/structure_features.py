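"""Structural featurization: Cα distance matrix → contact map → contact
graph → node2vec → pooled per-protein embedding.

The contact map marks residue pairs whose Cα atoms lie strictly closer than
``cmap_thresh`` (default 10 Å, the common Cα–Cα contact convention). The
contact graph is embedded with node2vec and residue vectors are mean-pooled
into one fixed-size vector per protein.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .containers import EmbeddingTable, ProteinStructure, WeightedGraph
from .graph_embedding import SkipGramConfig, WalkConfig, node2vec_embed

log = logging.getLogger(__name__)

#: canonical ordering of the 20 standard amino acids
STANDARD_ALPHABET = tuple("ACDEFGHIKLMNPQRSTVWY")

__all__ = [
    "STANDARD_ALPHABET",
    "distance_matrix",
    "one_hot_sequence",
    "contact_map",
    "structure_graph",
    "protein_structure_embedding",
]


def distance_matrix(coords: np.ndarray) -> np.ndarray:
    """Pairwise Euclidean distances (Å) between residue Cα coordinates."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] < 1:
        raise ValueError("coords must have shape (L, 3) with L >= 1")
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite coordinate")
    if coords.shape[0] == 1:
        return np.zeros((1, 1))
    return squareform(pdist(coords))


def one_hot_sequence(
    sequence: str, alphabet: tuple[str, ...] = STANDARD_ALPHABET
) -> np.ndarray:
    """L×V one-hot encoding; letters outside the alphabet give all-zero rows."""
    if not sequence:
        raise ValueError("empty sequence")
    if len(set(alphabet)) != len(alphabet):
        raise ValueError("alphabet has duplicate letters")
    index = {a: j for j, a in enumerate(alphabet)}
    S = np.zeros((len(sequence), len(alphabet)))
    for i, letter in enumerate(sequence):
        j = index.get(letter)
        if j is not None:
            S[i, j] = 1.0
    return S


def contact_map(D: np.ndarray, cmap_thresh: float) -> np.ndarray:
    """Binary contact map: A_ij = 1 iff D_ij < cmap_thresh and i != j."""
    if not cmap_thresh > 0:
        raise ValueError("cmap_thresh must be positive")
    D = np.asarray(D, dtype=float)
    A = (D < cmap_thresh).astype(np.int8)
    np.fill_diagonal(A, 0)
    return A


def structure_graph(A: np.ndarray) -> WeightedGraph:
    """Contact map → unit-weight residue graph with nodes "0" … "L-1"."""
    A = np.asarray(A)
    if A.shape[0] != A.shape[1] or not np.array_equal(A, A.T):
        raise ValueError("contact map must be square and symmetric")
    g = WeightedGraph.from_edges([], nodes=(str(i) for i in range(A.shape[0])))
    ii, jj = np.nonzero(np.triu(A, k=1))
    for i, j in zip(ii, jj):
        g.add_edge(str(i), str(j), 1.0)
    return g


def protein_structure_embedding(
    structure: ProteinStructure,
    cmap_thresh: float = 10.0,
    walk_cfg: WalkConfig = WalkConfig(),
    sg_cfg: SkipGramConfig = SkipGramConfig(),
    include_composition: bool = False,
) -> np.ndarray:
    """Fixed-size structural embedding of one protein.

    node2vec runs on the contact-graph topology; residue-node vectors are
    mean-pooled. A protein whose contact graph has no edges (e.g. a single
    residue) maps to the zero vector. With ``include_composition`` the mean
    one-hot amino-acid composition is appended.
    """
    A = contact_map(distance_matrix(structure.ca_coords), cmap_thresh)
    vec = np.zeros(sg_cfg.dim)
    if A.sum() == 0:
        log.warning(
            "%s: contact graph has no edges; structural embedding is zero",
            structure.protein_id,
        )
    else:
        table = node2vec_embed(structure_graph(A), walk_cfg, sg_cfg)
        vec = table.vectors.mean(axis=0)
    if include_composition:
        comp = one_hot_sequence(structure.sequence).mean(axis=0)
        vec = np.concatenate([vec, comp])
    return vec


def featurize_structures(
    structures: list[ProteinStructure],
    cmap_thresh: float = 10.0,
    walk_cfg: WalkConfig = WalkConfig(),
    sg_cfg: SkipGramConfig = SkipGramConfig(),
    include_composition: bool = False,
) -> EmbeddingTable:
    """Per-protein structural embedding table over a set of structures."""
    vecs = {
        s.protein_id: protein_structure_embedding(
            s, cmap_thresh, walk_cfg, sg_cfg, include_composition
        )
        for s in structures
    }
    return EmbeddingTable.from_dict(vecs)
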