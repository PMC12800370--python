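"""MLP link predictor for synthetic-lethal gene pairs.

Architecture: three ReLU hidden layers (256, 128, 64 units), sigmoid
output, dropout 0.5 after every hidden activation, binary cross-entropy
loss with an L2 penalty on the weight matrices (biases excluded). Training
uses Adam at an initial learning rate of 0.004, halving the rate when the
validation loss plateaus, with early stopping and best-epoch weight
restoration. Implemented directly in numpy so single-threaded runs are
bit-for-bit reproducible under a fixed seed.

The module also hosts the two experiment harnesses: the
positive:negative ratio sweep and the feature-block ablation study.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, f1_score, roc_auc_score

from .containers import EmbeddingTable, GeneProteinMap, canonical_pair
from .dataset_builder import (
    GeneFeatureTable,
    PairDataset,
    Standardizer,
    build_balanced_dataset,
    fuse_features,
    split_cv,
)
from .sequence_embedding import random_projection

__all__ = [
    "MLPConfig",
    "MLPModel",
    "MetricsReport",
    "loss",
    "train",
    "evaluate",
    "compute_metrics",
    "run_cv",
    "ratio_experiment",
    "ablation_experiment",
]

EPS = 1e-7


@dataclass(frozen=True)
class MLPConfig:
    hidden_sizes: tuple[int, ...] = (256, 128, 64)
    dropout_rate: float = 0.5
    learning_rate: float = 0.004
    l2_lambda: float = 1e-4
    max_epochs: int = 200
    patience: int = 10
    plateau_patience: int = 5
    plateau_factor: float = 0.5
    batch_size: int = 256
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.l2_lambda < 0:
            raise ValueError("l2_lambda must be non-negative")


class MLPModel:
    """Feed-forward network with per-layer weights W^(k) and biases b^(k)."""

    def __init__(self, input_dim: int, cfg: MLPConfig) -> None:
        self.cfg = cfg
        self.input_dim = input_dim
        rng = np.random.default_rng(cfg.seed)
        sizes = [input_dim, *cfg.hidden_sizes, 1]
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for d_in, d_out in zip(sizes[:-1], sizes[1:]):
            # He initialization, appropriate for ReLU hidden layers
            self.weights.append(rng.standard_normal((d_in, d_out)) * np.sqrt(2.0 / d_in))
            self.biases.append(np.zeros(d_out))

    def forward(
        self,
        x: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
        return_cache: bool = False,
    ):
        """Predicted link probability in (0,1) for each input row.

        With ``training`` on, inverted dropout is applied after each hidden
        activation; inference is deterministic.
        """
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != self.input_dim:
            raise ValueError(
                f"input dimension {x.shape[1]} != model input {self.input_dim}"
            )
        keep = 1.0 - self.cfg.dropout_rate
        cache: list[dict] = []
        h = x
        n_hidden = len(self.weights) - 1
        for k in range(n_hidden):
            z = h @ self.weights[k] + self.biases[k]
            a = np.maximum(z, 0.0)
            mask = None
            if training and self.cfg.dropout_rate > 0:
                if rng is None:
                    raise ValueError("training-mode forward needs an rng")
                mask = (rng.random(a.shape) < keep) / keep
                a = a * mask
            cache.append({"h_in": h, "z": z, "mask": mask})
            h = a
        z_out = h @ self.weights[-1] + self.biases[-1]
        p = 1.0 / (1.0 + np.exp(-z_out[:, 0]))
        p = np.clip(p, EPS, 1.0 - EPS)
        if return_cache:
            cache.append({"h_in": h})
            return p, cache
        return p

    def parameters(self) -> list[np.ndarray]:
        return self.weights + self.biases

    def set_parameters(self, params: list[np.ndarray]) -> None:
        n = len(self.weights)
        self.weights = [p.copy() for p in params[:n]]
        self.biases = [p.copy() for p in params[n:]]

    def save(self, path: str | Path, metadata: dict | None = None) -> None:
        """Persist weights, config and optional metadata in one .npz archive."""
        arrays = {f"W{k}": w for k, w in enumerate(self.weights)}
        arrays |= {f"b{k}": b for k, b in enumerate(self.biases)}
        arrays["config_json"] = np.frombuffer(
            json.dumps(
                {"cfg": asdict(self.cfg), "input_dim": self.input_dim,
                 "metadata": metadata or {}}
            ).encode(),
            dtype=np.uint8,
        )
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> tuple["MLPModel", dict]:
        data = np.load(path)
        meta = json.loads(bytes(data["config_json"]).decode())
        cfg_d = meta["cfg"]
        cfg_d["hidden_sizes"] = tuple(cfg_d["hidden_sizes"])
        model = cls(meta["input_dim"], MLPConfig(**cfg_d))
        n = len(model.weights)
        model.weights = [data[f"W{k}"] for k in range(n)]
        model.biases = [data[f"b{k}"] for k in range(n)]
        return model, meta["metadata"]


def loss(
    predictions: np.ndarray,
    labels: np.ndarray,
    model: MLPModel | None = None,
    l2_lambda: float = 0.0,
) -> float:
    """Binary cross-entropy plus λ Σ_k ‖W^k‖² over weight matrices.

    Predictions at exactly 0 or 1 are clamped at 1e-7. Biases are excluded
    from the penalty.
    """
    p = np.clip(np.asarray(predictions, dtype=float), EPS, 1.0 - EPS)
    y = np.asarray(labels, dtype=float)
    if p.shape != y.shape:
        raise ValueError("predictions and labels must have equal length")
    bce = -np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))
    penalty = 0.0
    if model is not None and l2_lambda > 0:
        penalty = l2_lambda * sum(float(np.sum(W**2)) for W in model.weights)
    return float(bce + penalty)


def _backward(
    model: MLPModel, cache: list[dict], p: np.ndarray, y: np.ndarray
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Gradients of (BCE + L2) w.r.t. weights and biases."""
    N = len(y)
    lam = model.cfg.l2_lambda
    grads_W: list[np.ndarray] = [None] * len(model.weights)  # type: ignore
    grads_b: list[np.ndarray] = [None] * len(model.biases)  # type: ignore
    delta = ((p - y) / N)[:, None]  # d BCE / d z_out
    h_last = cache[-1]["h_in"]
    grads_W[-1] = h_last.T @ delta + 2.0 * lam * model.weights[-1]
    grads_b[-1] = delta.sum(axis=0)
    upstream = delta @ model.weights[-1].T
    for k in range(len(model.weights) - 2, -1, -1):
        layer = cache[k]
        if layer["mask"] is not None:
            upstream = upstream * layer["mask"]
        upstream = upstream * (layer["z"] > 0)
        grads_W[k] = layer["h_in"].T @ upstream + 2.0 * lam * model.weights[k]
        grads_b[k] = upstream.sum(axis=0)
        if k > 0:
            upstream = upstream @ model.weights[k].T
    return grads_W, grads_b


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float) -> None:
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        for k, (p, g) in enumerate(zip(params, grads)):
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            m_hat = self.m[k] / (1 - self.b1**self.t)
            v_hat = self.v[k] / (1 - self.b2**self.t)
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def train(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    cfg: MLPConfig,
) -> tuple[MLPModel, pd.DataFrame]:
    """Train the MLP with Adam, plateau LR halving and early stopping.

    The validation loss (plain BCE, dropout off) drives both the learning-
    rate schedule (halve after ``plateau_patience`` epochs without
    improvement) and early stopping (``patience`` epochs); the best-
    validation-epoch weights are restored. Returns the model and a per-epoch
    history of train/val loss and learning rate.
    """
    if len(X_train) == 0 or len(X_val) == 0:
        raise ValueError("empty train or validation split")
    model = MLPModel(X_train.shape[1], cfg)
    rng = np.random.default_rng(cfg.seed + 1)
    opt = _Adam(model.parameters(), cfg.learning_rate)
    best_val = np.inf
    best_sched = np.inf
    best_params = [p.copy() for p in model.parameters()]
    since_improve = 0
    since_plateau = 0
    history = []
    y_train = np.asarray(y_train, dtype=float)
    y_val = np.asarray(y_val, dtype=float)
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(X_train))
        for lo in range(0, len(order), cfg.batch_size):
            sel = order[lo : lo + cfg.batch_size]
            p, cache = model.forward(
                X_train[sel], training=True, rng=rng, return_cache=True
            )
            grads_W, grads_b = _backward(model, cache, p, y_train[sel])
            opt.step(model.parameters(), grads_W + grads_b)
        train_loss = loss(
            model.forward(X_train), y_train, model, cfg.l2_lambda
        )
        val_loss = loss(model.forward(X_val), y_val)
        history.append(
            {"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss,
             "lr": opt.lr}
        )
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_params = [p.copy() for p in model.parameters()]
            since_improve = 0
        else:
            since_improve += 1
            if since_improve >= cfg.patience:
                break
        # the LR schedule uses a relative improvement threshold, so a slow
        # drift in validation loss still counts as a plateau
        if val_loss < best_sched * (1.0 - 1e-3):
            best_sched = val_loss
            since_plateau = 0
        else:
            since_plateau += 1
            if since_plateau >= cfg.plateau_patience:
                opt.lr *= cfg.plateau_factor
                since_plateau = 0
    model.set_parameters(best_params)
    return model, pd.DataFrame(history)


def compute_metrics(scores: np.ndarray, labels: np.ndarray) -> dict[str, float]:
    """AUC (ROC), AUPR (average precision) and F1 at threshold 0.5."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes required to compute AUC/AUPR")
    return {
        "auc": float(roc_auc_score(labels, scores)),
        "aupr": float(average_precision_score(labels, scores)),
        "f1": float(f1_score(labels, (np.asarray(scores) >= 0.5).astype(int))),
    }


def evaluate(model: MLPModel, X: np.ndarray, y: np.ndarray) -> dict[str, float]:
    if len(X) == 0:
        raise ValueError("empty evaluation split")
    return compute_metrics(model.forward(X), y)


def predict_pairs(
    model: MLPModel,
    features: GeneFeatureTable,
    pairs: list[tuple[str, str]],
    standardizer: Standardizer | None = None,
) -> np.ndarray:
    """Score arbitrary gene pairs; canonical gene ordering makes the score
    symmetric in the two genes."""
    X = np.stack(
        [
            np.concatenate(
                [features.table[a], features.table[b]]
                if (a, b) == canonical_pair(a, b)
                else [features.table[b], features.table[a]]
            )
            for a, b in (canonical_pair(a, b) for a, b in pairs)
        ]
    )
    if standardizer is not None:
        X = standardizer.transform(X)
    return model.forward(X)


@dataclass
class MetricsReport:
    """Per-fold AUC/AUPR/F1 with mean ± sd aggregation."""

    per_fold: list[dict[str, float]] = field(default_factory=list)

    def mean(self, metric: str) -> float:
        return float(np.mean([f[metric] for f in self.per_fold]))

    def sd(self, metric: str) -> float:
        return float(np.std([f[metric] for f in self.per_fold]))

    def summary(self) -> dict[str, dict[str, float]]:
        return {
            m: {"mean": self.mean(m), "sd": self.sd(m)}
            for m in ("auc", "aupr", "f1")
        }

    def to_json(self) -> str:
        return json.dumps({"per_fold": self.per_fold, "summary": self.summary()},
                          indent=2, sort_keys=True)


def run_cv(dataset: PairDataset, cfg: MLPConfig) -> MetricsReport:
    """Train and evaluate across every fold of a split dataset.

    Standardization statistics are fitted on each fold's training rows only;
    validation and test rows are transformed with the training statistics.
    """
    report = MetricsReport()
    for fold in range(dataset.n_folds):
        train_idx, val_idx, test_idx = dataset.fold_indices(fold)
        scaler = Standardizer().fit(dataset.X[train_idx])
        model, _ = train(
            scaler.transform(dataset.X[train_idx]),
            dataset.y[train_idx],
            scaler.transform(dataset.X[val_idx]),
            dataset.y[val_idx],
            cfg,
        )
        report.per_fold.append(
            evaluate(model, scaler.transform(dataset.X[test_idx]), dataset.y[test_idx])
        )
    return report


def ratio_experiment(
    positives: set[tuple[str, str]],
    known_negatives: set[tuple[str, str]],
    features: GeneFeatureTable,
    cfg: MLPConfig,
    ratios: tuple[tuple[int, int], ...] = ((1, 1), (1, 3), (1, 5), (1, 7)),
    folds: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """5-fold metrics at each positive:negative ratio, everything else fixed."""
    rows = []
    for m, n in ratios:
        ds = build_balanced_dataset(
            positives, known_negatives, features, ratio=(m, n), seed=seed
        )
        ds = split_cv(ds, folds=folds, seed=seed)
        rep = run_cv(ds, cfg)
        row = {"ratio": f"{m}:{n}"}
        for metric in ("auc", "aupr", "f1"):
            row[f"{metric}_mean"] = rep.mean(metric)
            row[f"{metric}_sd"] = rep.sd(metric)
        rows.append(row)
    return pd.DataFrame(rows)


def _dataset_with_features(
    base: PairDataset, features: GeneFeatureTable
) -> PairDataset:
    """Rebuild feature rows for the same pairs and fold assignments."""
    X = np.stack(
        [
            np.concatenate([features.table[a], features.table[b]])
            for a, b in zip(base.pairs["gene_a"], base.pairs["gene_b"])
        ]
    )
    return PairDataset(
        base.pairs, X, dict(features.block_dims),
        assignments=base.assignments, report=dict(base.report),
    )


def ablation_experiment(
    seq_table: EmbeddingTable,
    ppi_table: EmbeddingTable,
    struct_table: EmbeddingTable,
    gene_map: GeneProteinMap,
    positives: set[tuple[str, str]],
    known_negatives: set[tuple[str, str]],
    cfg: MLPConfig,
    reduced_dim: int = 128,
    folds: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Feature-block ablation under identical pairs, folds and seeds.

    Variants: the full model (native sequence dimension), the reduced model
    with the sequence block projected to ``reduced_dim``, and the reduced
    model with each single block removed. All variants share one negative
    sample and one fold assignment, so differences are attributable to the
    features alone.
    """
    full = fuse_features(seq_table, ppi_table, struct_table, gene_map)
    if seq_table.dim > reduced_dim:
        proj = random_projection(seq_table.dim, reduced_dim, seed=seed)
        reduced = full.project_block("seq", proj)
    else:
        reduced = full
    variants = {
        "full": full,
        "reduced": reduced,
        "non_struct": reduced.drop_block("struct"),
        "non_seq": reduced.drop_block("seq"),
        "non_ppi": reduced.drop_block("ppi"),
    }
    base = build_balanced_dataset(
        positives, known_negatives, full, ratio=(1, 1), seed=seed
    )
    base = split_cv(base, folds=folds, seed=seed)
    rows = []
    for name, feats in variants.items():
        ds = _dataset_with_features(base, feats)
        rep = run_cv(ds, cfg)
        row = {"variant": name, "input_dim": 2 * feats.dim}
        for metric in ("auc", "aupr", "f1"):
            row[f"{metric}_mean"] = rep.mean(metric)
            row[f"{metric}_sd"] = rep.sd(metric)
        rows.append(row)
    return pd.DataFrame(rows)
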