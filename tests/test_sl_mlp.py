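"""The MLP link predictor: forward pass, loss, training, metrics."""

import numpy as np
import pytest

from synlethal.containers import EmbeddingTable
from synlethal.dataset_builder import GeneFeatureTable, Standardizer
from synlethal.sl_mlp import (
    MLPConfig,
    MLPModel,
    compute_metrics,
    evaluate,
    loss,
    predict_pairs,
    train,
)


def reference_auc(scores, labels):
    """Concordance-count AUC (ties count half)."""
    scores, labels = np.asarray(scores), np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def reference_average_precision(scores, labels):
    """Step-wise AP: sum over recall increments of precision."""
    order = np.argsort(-np.asarray(scores), kind="stable")
    labels = np.asarray(labels)[order]
    scores = np.asarray(scores)[order]
    n_pos = labels.sum()
    ap, tp, fp = 0.0, 0, 0
    i = 0
    while i < len(labels):
        j = i
        while j < len(labels) and scores[j] == scores[i]:
            j += 1
        tp_new = tp + labels[i:j].sum()
        fp_new = fp + (j - i) - labels[i:j].sum()
        if tp_new > tp:
            ap += (tp_new - tp) / n_pos * (tp_new / (tp_new + fp_new))
        tp, fp = tp_new, fp_new
        i = j
    return ap


def reference_f1(scores, labels, thresh=0.5):
    pred = (np.asarray(scores) >= thresh).astype(int)
    labels = np.asarray(labels)
    tp = int(((pred == 1) & (labels == 1)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    if tp == 0:
        return 0.0
    prec, rec = tp / (tp + fp), tp / (tp + fn)
    return 2 * prec * rec / (prec + rec)


class TestForward:
    def test_zero_weights_give_half(self):
        model = MLPModel(6, MLPConfig(hidden_sizes=(4,), seed=0))
        for W in model.weights:
            W[:] = 0.0
        out = model.forward(np.random.default_rng(0).standard_normal((5, 6)))
        np.testing.assert_allclose(out, 0.5)

    def test_inference_deterministic(self):
        model = MLPModel(8, MLPConfig(seed=1))
        x = np.random.default_rng(1).standard_normal((3, 8))
        np.testing.assert_array_equal(model.forward(x), model.forward(x))

    def test_hand_computed_relu_sigmoid_chain(self):
        # 2 inputs -> 2 hidden (ReLU) -> 1 output (sigmoid), dropout off
        model = MLPModel(2, MLPConfig(hidden_sizes=(2,), dropout_rate=0.0, seed=0))
        model.weights[0][:] = np.array([[1.0, -1.0], [2.0, 0.5]])
        model.biases[0][:] = np.array([0.5, -0.5])
        model.weights[1][:] = np.array([[1.0], [-2.0]])
        model.biases[1][:] = np.array([0.25])
        x = np.array([1.0, -1.0])
        h = np.maximum(x @ model.weights[0] + model.biases[0], 0)  # [0, 0]
        z = h @ model.weights[1] + model.biases[1]  # 0.25
        expect = 1 / (1 + np.exp(-z[0]))
        assert model.forward(x)[0] == pytest.approx(expect, abs=1e-12)

    def test_dimension_mismatch(self):
        model = MLPModel(4, MLPConfig(seed=0))
        with pytest.raises(ValueError, match="dimension"):
            model.forward(np.ones((2, 5)))

    def test_checkpoint_roundtrip(self, tmp_path):
        model = MLPModel(6, MLPConfig(hidden_sizes=(8, 4), seed=3))
        x = np.random.default_rng(3).standard_normal((4, 6))
        model.save(tmp_path / "m.npz", metadata={"note": "test"})
        back, meta = MLPModel.load(tmp_path / "m.npz")
        assert meta == {"note": "test"}
        np.testing.assert_array_equal(model.forward(x), back.forward(x))


class TestLoss:
    def test_perfect_predictions_near_zero(self):
        y = np.array([1.0, 0.0, 1.0])
        assert loss(y, y) < 1e-5

    def test_uniform_half_is_ln_two(self):
        y = np.array([1, 0, 1, 0], dtype=float)
        assert loss(np.full(4, 0.5), y) == pytest.approx(np.log(2), abs=1e-12)

    def test_matches_loop_oracle_with_l2(self):
        rng = np.random.default_rng(2)
        model = MLPModel(5, MLPConfig(hidden_sizes=(3,), seed=2))
        p = rng.uniform(0.01, 0.99, 40)
        y = (rng.random(40) < 0.5).astype(float)
        lam = 0.37
        bce = -sum(
            yi * np.log(pi) + (1 - yi) * np.log(1 - pi) for pi, yi in zip(p, y)
        ) / 40
        pen = lam * sum(float((W**2).sum()) for W in model.weights)
        assert loss(p, y, model, lam) == pytest.approx(bce + pen, abs=1e-9)

    def test_zero_lambda_reduces_to_bce(self):
        rng = np.random.default_rng(4)
        model = MLPModel(5, MLPConfig(seed=4))
        p = rng.uniform(0.01, 0.99, 20)
        y = (rng.random(20) < 0.5).astype(float)
        assert loss(p, y, model, 0.0) == pytest.approx(loss(p, y), abs=1e-15)

    def test_extreme_predictions_clamped(self):
        val = loss(np.array([0.0, 1.0]), np.array([0.0, 1.0]))
        assert np.isfinite(val)


class TestMetrics:
    def test_perfect_separation(self):
        m = compute_metrics([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert m == {"auc": 1.0, "aupr": 1.0, "f1": 1.0}

    def test_pair_enumeration_auc(self):
        # labels [1,0,1,0] on scores [0.9,0.8,0.3,0.1]: 3 of 4 pairs concordant
        m = compute_metrics([0.9, 0.8, 0.3, 0.1], [1, 0, 1, 0])
        assert m["auc"] == pytest.approx(0.75)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            compute_metrics([0.5, 0.6], [1, 1])

    @pytest.mark.parametrize("trial", range(4))
    def test_matches_reference_implementations(self, trial):
        rng = np.random.default_rng(trial)
        for _ in range(75):
            n = int(rng.integers(4, 40))
            labels = np.zeros(n, dtype=int)
            labels[: int(rng.integers(1, n))] = 1
            rng.shuffle(labels)
            if labels.sum() in (0, n):
                continue
            scores = np.round(rng.random(n), 2)  # coarse grid to exercise ties
            m = compute_metrics(scores, labels)
            assert m["auc"] == pytest.approx(reference_auc(scores, labels), abs=1e-9)
            assert m["aupr"] == pytest.approx(
                reference_average_precision(scores, labels), abs=1e-9
            )
            assert m["f1"] == pytest.approx(reference_f1(scores, labels), abs=1e-9)


def separable_data(n=300, d=10, seed=0):
    rng = np.random.default_rng(seed)
    y = (rng.random(n) < 0.5).astype(float)
    X = rng.standard_normal((n, d)) + 2.5 * y[:, None]
    return X, y


class TestTrain:
    def test_learns_separable_data(self):
        X, y = separable_data()
        cfg = MLPConfig(hidden_sizes=(16, 8), batch_size=32, max_epochs=60, seed=0)
        model, _ = train(X[:200], y[:200], X[200:250], y[200:250], cfg)
        m = evaluate(model, X[250:], y[250:])
        assert m["auc"] >= 0.95

    def test_training_loss_decreases_initially(self):
        X, y = separable_data(seed=1)
        cfg = MLPConfig(hidden_sizes=(16,), batch_size=32, max_epochs=5, seed=1)
        _, hist = train(X[:200], y[:200], X[200:250], y[200:250], cfg)
        assert hist["train_loss"].iloc[-1] < hist["train_loss"].iloc[0]

    def test_bitwise_deterministic_history(self):
        X, y = separable_data(seed=2)
        cfg = MLPConfig(hidden_sizes=(8,), batch_size=64, max_epochs=10, seed=2)
        _, h1 = train(X[:200], y[:200], X[200:], y[200:], cfg)
        _, h2 = train(X[:200], y[:200], X[200:], y[200:], cfg)
        assert h1.equals(h2)

    def test_lr_schedule_halves_on_plateau(self):
        # constant inputs admit no improvement beyond the base rate, so the
        # validation loss plateaus and the learning rate must decay
        rng = np.random.default_rng(3)
        X = np.zeros((120, 6))
        y = (rng.random(120) < 0.5).astype(float)
        cfg = MLPConfig(
            hidden_sizes=(4,), batch_size=32, max_epochs=40,
            patience=40, plateau_patience=3, seed=3,
        )
        _, hist = train(X[:80], y[:80], X[80:], y[80:], cfg)
        assert hist["lr"].iloc[-1] < cfg.learning_rate

    def test_empty_split_errors(self):
        with pytest.raises(ValueError):
            train(np.empty((0, 3)), np.empty(0), np.ones((2, 3)), np.ones(2),
                  MLPConfig(seed=0))


class TestPredictPairs:
    def test_symmetric_in_gene_order(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(6)]
        feats = GeneFeatureTable(
            EmbeddingTable(genes, rng.standard_normal((6, 4))),
            {"seq": 4, "ppi": 0, "struct": 0},
        )
        model = MLPModel(8, MLPConfig(hidden_sizes=(4,), seed=5))
        scaler = Standardizer().fit(rng.standard_normal((10, 8)))
        fwd = predict_pairs(model, feats, [("g1", "g4"), ("g2", "g0")], scaler)
        rev = predict_pairs(model, feats, [("g4", "g1"), ("g0", "g2")], scaler)
        np.testing.assert_array_equal(fwd, rev)
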