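"""Sequence featurization from per-residue, per-layer contextual embeddings.

A residue embedder (the contract) maps an amino-acid sequence to a tensor
of shape (layers+1, T, d_model). The pooled protein vector is the residue
mean within each layer followed by an element-wise sum across layers.

A pre-trained protein language model (ELMo/SeqVec-style) is one realization
of the contract; the built-in k-mer hash embedder is a deterministic,
offline realization used throughout the tests: each residue's vector is a
seeded hash of the k-mer centered on it, so similar sequences share
components while the mapping stays reproducible.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = [
    "EmbedderContract",
    "mean_over_timesteps",
    "aggregate_layers",
    "sequence_embedding",
    "kmer_hash_embedder",
    "random_projection",
]


@dataclass(frozen=True)
class EmbedderContract:
    """A deterministic map sequence → (layers+1, T, d_model) tensor."""

    embed: Callable[[str], np.ndarray]
    d_model: int
    layers: int

    def __call__(self, sequence: str) -> np.ndarray:
        tensor = np.asarray(self.embed(sequence), dtype=float)
        expected = (self.layers + 1, len(sequence), self.d_model)
        if tensor.shape != expected:
            raise ValueError(
                f"embedder returned shape {tensor.shape}, expected {expected}"
            )
        if not np.all(np.isfinite(tensor)):
            raise ValueError("non-finite residue embedding")
        return tensor


def mean_over_timesteps(layer_matrix: np.ndarray) -> np.ndarray:
    """Mean of the T per-residue vectors of one layer: (1/T) Σ_t h_t."""
    layer_matrix = np.asarray(layer_matrix, dtype=float)
    if layer_matrix.ndim != 2 or layer_matrix.shape[0] == 0:
        raise ValueError("layer matrix must be (T, d_model) with T >= 1")
    return layer_matrix.mean(axis=0)


def aggregate_layers(per_layer_vectors: list[np.ndarray]) -> np.ndarray:
    """Element-wise sum of the per-layer pooled vectors."""
    if not per_layer_vectors:
        raise ValueError("need at least one layer")
    dims = {np.asarray(v).shape for v in per_layer_vectors}
    if len(dims) > 1:
        raise ValueError(f"ragged layer dimensions: {sorted(dims)}")
    return np.sum([np.asarray(v, dtype=float) for v in per_layer_vectors], axis=0)


def sequence_embedding(sequence: str, embedder: EmbedderContract) -> np.ndarray:
    """Fixed-size protein vector: per-layer residue mean, then layer sum."""
    if not sequence:
        raise ValueError("empty sequence")
    tensor = embedder(sequence)
    return aggregate_layers([mean_over_timesteps(layer) for layer in tensor])


def _kmer_vector(kmer: str, layer: int, d_model: int, seed: int) -> np.ndarray:
    digest = hashlib.blake2b(
        f"{seed}:{layer}:{kmer}".encode(), digest_size=8
    ).digest()
    rng = np.random.default_rng(int.from_bytes(digest, "little"))
    return rng.uniform(-1.0, 1.0, d_model)


def kmer_hash_embedder(
    k: int = 3, d_model: int = 1024, layers: int = 2, seed: int = 0
) -> EmbedderContract:
    """Deterministic residue embedder hashing the k-mer centered at each site.

    Sequences are padded with '-' at the termini so every residue has a
    k-mer; a single-site substitution therefore perturbs at most k residue
    rows, and shared k-mers yield identical rows.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    half = (k - 1) // 2

    def embed(sequence: str) -> np.ndarray:
        padded = "-" * half + sequence + "-" * (k - 1 - half)
        T = len(sequence)
        out = np.empty((layers + 1, T, d_model))
        for layer in range(layers + 1):
            for i in range(T):
                out[layer, i] = _kmer_vector(
                    padded[i : i + k], layer, d_model, seed
                )
        return out

    return EmbedderContract(embed=embed, d_model=d_model, layers=layers)


def random_projection(d_in: int, d_out: int, seed: int = 0) -> np.ndarray:
    """Seeded random orthonormal projection matrix (d_in × d_out), d_out ≤ d_in.

    Used to reduce the high-dimensional sequence block to match the other
    feature blocks in the reduced-dimension model variant.
    """
    if d_out > d_in:
        raise ValueError("d_out must not exceed d_in")
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.standard_normal((d_in, d_out)))
    return q
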