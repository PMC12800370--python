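"""Gene-level dataset assembly: feature fusion, constrained random negative
sampling, balanced pair datasets, cross-validation splits, standardization.

Valid genes are those with all three feature blocks (sequence, PPI,
structure) present for their mapped protein. Negative pairs are drawn
uniformly from the valid-gene pair space excluding every known SL and
non-SL pair in either orientation. Each fold of the 5-fold protocol splits
the data 64% train / 16% validation / 20% test (6.4:1.6:2), stratified by
label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split

from .containers import EmbeddingTable, GeneProteinMap, canonical_pair

__all__ = [
    "GeneFeatureTable",
    "PairDataset",
    "Standardizer",
    "resolve_gene_map",
    "fuse_features",
    "sample_negatives",
    "build_balanced_dataset",
    "split_cv",
]

BLOCK_ORDER = ("seq", "ppi", "struct")


def resolve_gene_map(
    entries: list[tuple[str, str]], sequences: dict[str, str] | None = None
) -> GeneProteinMap:
    """Collapse a possibly many-to-many gene↔protein map to one-to-one.

    When a gene maps to several proteins, the protein with the longest known
    sequence wins (ties → lexicographically smallest protein ID); without
    sequence information the first mapping in file order wins.
    """
    resolved: dict[str, str] = {}
    for gene, protein in entries:
        if gene not in resolved:
            resolved[gene] = protein
            continue
        if sequences is None:
            continue
        incumbent = resolved[gene]
        key_new = (len(sequences.get(protein, "")), protein)
        key_old = (len(sequences.get(incumbent, "")), incumbent)
        # longer sequence wins; among equals keep the smaller ID
        if key_new[0] > key_old[0] or (key_new[0] == key_old[0] and protein < incumbent):
            resolved[gene] = protein
    return GeneProteinMap(resolved)


@dataclass
class GeneFeatureTable:
    """Per-gene concatenated feature vectors [seq | ppi | struct]."""

    table: EmbeddingTable
    block_dims: dict[str, int]
    n_excluded: int = 0

    @property
    def genes(self) -> list[str]:
        return self.table.ids

    @property
    def dim(self) -> int:
        return self.table.dim

    def block_slice(self, block: str) -> slice:
        lo = 0
        for name in BLOCK_ORDER:
            d = self.block_dims.get(name, 0)
            if name == block:
                return slice(lo, lo + d)
            lo += d
        raise KeyError(block)

    def drop_block(self, block: str) -> "GeneFeatureTable":
        """Ablation helper: remove one feature block, keeping gene order."""
        if block not in self.block_dims or self.block_dims[block] == 0:
            raise KeyError(f"no block {block!r} to drop")
        keep = np.ones(self.dim, dtype=bool)
        keep[self.block_slice(block)] = False
        if not keep.any():
            raise ValueError("cannot drop the last feature block")
        dims = {k: (0 if k == block else d) for k, d in self.block_dims.items()}
        return GeneFeatureTable(
            EmbeddingTable(self.genes, self.table.vectors[:, keep]),
            dims,
            self.n_excluded,
        )

    def project_block(self, block: str, projection: np.ndarray) -> "GeneFeatureTable":
        """Replace one block by its image under a projection matrix."""
        sl = self.block_slice(block)
        if projection.shape[0] != sl.stop - sl.start:
            raise ValueError("projection rows must match block dimension")
        parts = []
        dims = dict(self.block_dims)
        lo = 0
        for name in BLOCK_ORDER:
            d = self.block_dims.get(name, 0)
            blockmat = self.table.vectors[:, lo : lo + d]
            if name == block:
                blockmat = blockmat @ projection
                dims[name] = projection.shape[1]
            parts.append(blockmat)
            lo += d
        return GeneFeatureTable(
            EmbeddingTable(self.genes, np.concatenate(parts, axis=1)),
            dims,
            self.n_excluded,
        )


def fuse_features(
    seq_table: EmbeddingTable,
    ppi_table: EmbeddingTable,
    struct_table: EmbeddingTable,
    gene_map: GeneProteinMap,
) -> GeneFeatureTable:
    """Concatenate the three protein-level blocks into gene vectors.

    Genes whose protein lacks any block are excluded and counted.
    """
    fused: dict[str, np.ndarray] = {}
    n_excluded = 0
    for gene in sorted(gene_map.entries):
        protein = gene_map.protein_for(gene)
        if protein in seq_table and protein in ppi_table and protein in struct_table:
            fused[gene] = np.concatenate(
                [seq_table[protein], ppi_table[protein], struct_table[protein]]
            )
        else:
            n_excluded += 1
    if not fused:
        raise ValueError("no gene has all three feature blocks")
    return GeneFeatureTable(
        EmbeddingTable.from_dict(fused),
        {"seq": seq_table.dim, "ppi": ppi_table.dim, "struct": struct_table.dim},
        n_excluded,
    )


def sample_negatives(
    valid_genes: set[str],
    positives: set[tuple[str, str]],
    known_negatives: set[tuple[str, str]],
    target: int,
    seed: int,
) -> list[tuple[str, str]]:
    """Draw ``target`` distinct random gene pairs disjoint from P ∪ N.

    Pairs are canonical, drawn uniformly from the C(|V|,2) pair space of the
    valid genes excluding self-pairs and every known pair in either
    orientation. Deterministic given the seed.
    """
    genes = sorted(valid_genes)
    n = len(genes)
    forbidden = {canonical_pair(*p) for p in positives | known_negatives
                 if p[0] in valid_genes and p[1] in valid_genes}
    n_candidates = n * (n - 1) // 2 - len(forbidden)
    if target > n_candidates:
        raise ValueError(
            f"cannot sample {target} negatives: only {n_candidates} "
            f"candidate pairs remain"
        )
    rng = np.random.default_rng(seed)
    chosen: set[tuple[str, str]] = set()
    out: list[tuple[str, str]] = []
    # rejection sampling; falls back to full enumeration when the remaining
    # candidate space is small relative to the request
    max_attempts = 200 * max(target, 1)
    attempts = 0
    while len(out) < target and attempts < max_attempts:
        i, j = rng.integers(0, n, size=2)
        attempts += 1
        if i == j:
            continue
        pair = canonical_pair(genes[i], genes[j])
        if pair in forbidden or pair in chosen:
            continue
        chosen.add(pair)
        out.append(pair)
    if len(out) < target:
        pool = [
            (genes[i], genes[j])
            for i in range(n)
            for j in range(i + 1, n)
            if (genes[i], genes[j]) not in forbidden
            and (genes[i], genes[j]) not in chosen
        ]
        extra = rng.choice(len(pool), size=target - len(out), replace=False)
        out.extend(pool[k] for k in sorted(extra))
    return out


@dataclass
class PairDataset:
    """Labeled gene pairs with concatenated feature vectors and CV splits.

    ``pairs`` has columns gene_a, gene_b (canonical order) and label (1 = SL).
    ``X`` holds one row per pair: concat(features[gene_a], features[gene_b]).
    ``assignments`` (set by :func:`split_cv`) is long-format with one row per
    (pair row, fold) carrying split ∈ {train, val, test}.
    """

    pairs: pd.DataFrame
    X: np.ndarray
    block_dims: dict[str, int]
    assignments: pd.DataFrame | None = None
    report: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def y(self) -> np.ndarray:
        return self.pairs["label"].to_numpy()

    @property
    def n_folds(self) -> int:
        if self.assignments is None:
            raise ValueError("dataset has no CV splits; call split_cv first")
        return int(self.assignments["fold"].max()) + 1

    def fold_indices(self, fold: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        if self.assignments is None:
            raise ValueError("dataset has no CV splits; call split_cv first")
        sub = self.assignments[self.assignments["fold"] == fold]
        out = []
        for split in ("train", "val", "test"):
            out.append(sub.loc[sub["split"] == split, "row"].to_numpy())
        return tuple(out)  # type: ignore[return-value]


def build_balanced_dataset(
    positives: set[tuple[str, str]],
    known_negatives: set[tuple[str, str]],
    features: GeneFeatureTable,
    ratio: tuple[int, int] = (1, 1),
    seed: int = 0,
) -> PairDataset:
    """Assemble the labeled pair dataset at a positive:negative ratio m:n.

    Positives are the known SL pairs restricted to the valid-gene set. All
    usable known non-SL pairs are taken first (subsampled uniformly when
    over-supplied); random negatives fill the remainder. Each pair's feature
    vector concatenates the two gene vectors in canonical gene-ID order.
    """
    m, n = ratio
    if m < 1 or n < 1:
        raise ValueError("ratio parts must be positive integers")
    valid = set(features.genes)
    pos = sorted(
        canonical_pair(*p) for p in positives if p[0] in valid and p[1] in valid
    )
    if not pos:
        raise ValueError("no positive pair is covered by the feature table")
    needed = round(len(pos) * n / m)
    known = sorted(
        canonical_pair(*p)
        for p in known_negatives
        if p[0] in valid and p[1] in valid
    )
    rng = np.random.default_rng(seed)
    if len(known) >= needed:
        keep = rng.choice(len(known), size=needed, replace=False)
        neg = [known[k] for k in sorted(keep)]
        n_sampled = 0
    else:
        sampled = sample_negatives(
            valid, set(pos), set(known), needed - len(known), seed
        )
        neg = known + sampled
        n_sampled = len(sampled)

    rows = [(a, b, 1) for a, b in pos] + [(a, b, 0) for a, b in neg]
    pairs = pd.DataFrame(rows, columns=["gene_a", "gene_b", "label"])
    X = np.stack(
        [
            np.concatenate([features.table[a], features.table[b]])
            for a, b, _ in rows
        ]
    )
    report = {
        "n_valid_genes": len(valid),
        "n_positives": len(pos),
        "n_known_negatives_used": len(neg) - n_sampled,
        "n_negatives_sampled": n_sampled,
        "ratio": f"{m}:{n}",
    }
    return PairDataset(pairs, X, dict(features.block_dims), report=report)


def split_cv(dataset: PairDataset, folds: int = 5, seed: int = 0) -> PairDataset:
    """Assign 5-fold train/val/test splits in a 6.4:1.6:2 proportion.

    Per fold: that fold's share (1/folds) is the test set; the remainder is
    split 80/20 into train/val. Both splits are stratified by label and
    deterministic given the seed. Test sets across folds partition the data.
    """
    y = dataset.y
    if len(dataset) < folds:
        raise ValueError("fewer rows than folds")
    if min(np.bincount(y, minlength=2)) < folds:
        raise ValueError("too few rows in one class to stratify")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    records = []
    for fold, (rest_idx, test_idx) in enumerate(skf.split(dataset.X, y)):
        train_idx, val_idx = train_test_split(
            rest_idx,
            test_size=0.2,
            stratify=y[rest_idx],
            random_state=(seed * folds + fold + 1) % (2**31 - 1),
        )
        for idx, split in ((train_idx, "train"), (val_idx, "val"), (test_idx, "test")):
            for row in idx:
                records.append((int(row), fold, split))
    dataset.assignments = pd.DataFrame(records, columns=["row", "fold", "split"])
    return dataset


class Standardizer:
    """Per-dimension z-scoring fit on training rows only.

    Dimensions with zero standard deviation pass through unscaled.
    """

    def __init__(self) -> None:
        self.mean_: np.ndarray | None = None
        self.scale_: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "Standardizer":
        X = np.asarray(X, dtype=float)
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0)
        self.scale_ = np.where(sd > 0, sd, 1.0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise ValueError("Standardizer is not fitted")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.mean_.shape[0]:
            raise ValueError("dimension mismatch")
        return (X - self.mean_) / self.scale_

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)

    def inverse_transform(self, Z: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise ValueError("Standardizer is not fitted")
        return np.asarray(Z, dtype=float) * self.scale_ + self.mean_
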