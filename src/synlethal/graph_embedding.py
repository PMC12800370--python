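"""node2vec graph embedding: second-order biased random walks + skip-gram.

Shared by the PPI branch (protein nodes) and the structure branch (residue
nodes of a contact graph). Walks follow the second-order bias of Grover &
Leskovec: from state (prev → curr), candidate u gets unnormalized weight
w(curr,u) · α where α = 1/p if u is prev, 1 if u is adjacent to prev, and
1/q otherwise. Skip-gram with negative sampling is trained on the walk
corpus by minibatch SGD; with a fixed seed and single-threaded numpy the
output is bit-for-bit reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import EmbeddingTable, WeightedGraph

__all__ = [
    "WalkConfig",
    "SkipGramConfig",
    "transition_distribution",
    "simulate_walks",
    "train_skipgram",
    "node2vec_embed",
]


@dataclass(frozen=True)
class WalkConfig:
    p: float = 1.0
    q: float = 1.0
    walks_per_node: int = 10
    walk_length: int = 80
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.p > 0 and self.q > 0):
            raise ValueError("p and q must be strictly positive")
        if self.walks_per_node < 1 or self.walk_length < 1:
            raise ValueError("walks_per_node and walk_length must be >= 1")


@dataclass(frozen=True)
class SkipGramConfig:
    dim: int = 128
    window: int = 10
    epochs: int = 5
    negative: int = 5
    alpha: float = 0.025  # initial SGD learning rate, linearly decayed
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dim < 1:
            raise ValueError("dim must be >= 1")
        if self.window < 1 or self.epochs < 1 or self.negative < 0:
            raise ValueError("invalid skip-gram configuration")


def transition_distribution(
    graph: WeightedGraph,
    prev: str | None,
    curr: str,
    p: float,
    q: float,
) -> dict[str, float]:
    """Exact next-step distribution of the biased second-order walk.

    On the first step (prev is None) the bias is absent and the walk moves
    proportionally to edge weights alone.
    """
    nbrs = graph.neighbors(curr)
    if not nbrs:
        raise ValueError(f"node {curr!r} has no neighbors")
    if prev is not None and prev not in nbrs:
        raise ValueError(f"prev {prev!r} is not adjacent to curr {curr!r}")
    weights = {}
    for u, w in nbrs.items():
        if prev is None:
            alpha = 1.0
        elif u == prev:
            alpha = 1.0 / p
        elif graph.has_edge(u, prev):
            alpha = 1.0
        else:
            alpha = 1.0 / q
        weights[u] = w * alpha
    total = sum(weights.values())
    return {u: w / total for u, w in weights.items()}


def simulate_walks(graph: WeightedGraph, cfg: WalkConfig) -> list[list[str]]:
    """Sample ``walks_per_node`` biased walks of length ``walk_length`` per node.

    A walk truncates early only at a node with no neighbors. Deterministic
    given the seed.
    """
    nodes = graph.nodes
    if not nodes:
        raise ValueError("empty graph")
    rng = np.random.default_rng(cfg.seed)
    # pre-index neighbors for O(deg) candidate weighting per step
    nbr_ids: dict[str, list[str]] = {n: sorted(graph.neighbors(n)) for n in nodes}
    nbr_w: dict[str, np.ndarray] = {
        n: np.array([graph.neighbors(n)[u] for u in nbr_ids[n]]) for n in nodes
    }
    nbr_set: dict[str, set[str]] = {n: set(nbr_ids[n]) for n in nodes}

    walks: list[list[str]] = []
    inv_p, inv_q = 1.0 / cfg.p, 1.0 / cfg.q
    for _ in range(cfg.walks_per_node):
        for start in nodes:
            walk = [start]
            while len(walk) < cfg.walk_length:
                curr = walk[-1]
                cands = nbr_ids[curr]
                if not cands:
                    break
                w = nbr_w[curr].copy()
                if len(walk) > 1:
                    prev = walk[-2]
                    prev_nbrs = nbr_set[prev]
                    for k, u in enumerate(cands):
                        if u == prev:
                            w[k] *= inv_p
                        elif u not in prev_nbrs:
                            w[k] *= inv_q
                walk.append(cands[rng.choice(len(cands), p=w / w.sum())])
            walks.append(walk)
    return walks


def _walk_pairs(
    walks: list[list[str]], index: dict[str, int], window: int
) -> np.ndarray:
    """All (center, context) index pairs within the window, both directions."""
    pairs: list[tuple[int, int]] = []
    for walk in walks:
        idx = [index[n] for n in walk]
        for i, c in enumerate(idx):
            for j in range(max(0, i - window), min(len(idx), i + window + 1)):
                if j != i:
                    pairs.append((c, idx[j]))
    return np.asarray(pairs, dtype=np.int64).reshape(-1, 2)


def train_skipgram(walks: list[list[str]], cfg: SkipGramConfig) -> EmbeddingTable:
    """Train skip-gram with negative sampling on a walk corpus.

    Negatives are drawn from the unigram distribution raised to 3/4, the
    standard smoothing. Minibatch SGD with a linearly decayed learning rate;
    gradient collisions within a batch are accumulated exactly.
    """
    if not walks or not any(walks):
        raise ValueError("empty walk corpus")
    vocab = sorted({n for walk in walks for n in walk})
    index = {n: k for k, n in enumerate(vocab)}
    V, d = len(vocab), cfg.dim
    rng = np.random.default_rng(cfg.seed)

    counts = np.zeros(V)
    for walk in walks:
        for n in walk:
            counts[index[n]] += 1
    noise = counts**0.75
    noise /= noise.sum()

    w_in = (rng.random((V, d)) - 0.5) / d
    w_out = np.zeros((V, d))

    pairs = _walk_pairs(walks, index, cfg.window)
    n_pairs = len(pairs)
    if n_pairs == 0:  # corpus of isolated length-1 walks
        return EmbeddingTable(vocab, w_in)

    batch = 1024
    total_steps = cfg.epochs * ((n_pairs + batch - 1) // batch)
    step = 0
    min_alpha = cfg.alpha * 1e-3
    for _ in range(cfg.epochs):
        order = rng.permutation(n_pairs)
        for lo in range(0, n_pairs, batch):
            sel = pairs[order[lo : lo + batch]]
            centers, contexts = sel[:, 0], sel[:, 1]
            B = len(centers)
            lr = cfg.alpha + (min_alpha - cfg.alpha) * (step / max(1, total_steps - 1))
            step += 1

            if cfg.negative > 0:
                negs = rng.choice(V, size=(B, cfg.negative), p=noise)
                targets = np.concatenate([contexts[:, None], negs], axis=1)
            else:
                targets = contexts[:, None]
            labels = np.zeros_like(targets, dtype=float)
            labels[:, 0] = 1.0

            h = w_in[centers]  # (B, d)
            out = w_out[targets]  # (B, 1+neg, d)
            scores = np.clip(np.einsum("bd,bkd->bk", h, out), -35.0, 35.0)
            g = (1.0 / (1.0 + np.exp(-scores)) - labels) * lr  # (B, 1+neg)

            grad_h = np.einsum("bk,bkd->bd", g, out)
            grad_out = g[:, :, None] * h[:, None, :]
            np.add.at(w_in, centers, -grad_h)
            np.add.at(w_out, targets.ravel(),
                      -grad_out.reshape(-1, d))
    return EmbeddingTable(vocab, w_in)


def node2vec_embed(
    graph: WeightedGraph, walk_cfg: WalkConfig, sg_cfg: SkipGramConfig
) -> EmbeddingTable:
    """Embed every node of a graph: biased walks, then skip-gram."""
    return train_skipgram(simulate_walks(graph, walk_cfg), sg_cfg)
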