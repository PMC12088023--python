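"""The fully connected head: activations, loss, gradients, training."""

import math

import numpy as np
import pytest
from sklearn.base import clone
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from histotile.backbone import FeatureVector
from histotile.head import (
    HeadNetClassifier,
    TrainConfig,
    _Adam,
    cross_entropy,
    head_gradients,
    head_loss,
    init_head,
    load_head,
    predict_proba,
    predict_proba_batch,
    relu,
    save_head,
    softmax,
    train_head,
)
from histotile.types import HeadParams, Label


class TestActivations:
    def test_relu_by_cases(self):
        assert np.array_equal(relu([-3, 0, 2]), [0, 0, 2])
        assert np.array_equal(relu([-5.0, -0.1]), [0.0, 0.0])

    def test_relu_idempotent(self, rng):
        x = rng.normal(size=100)
        assert np.array_equal(relu(relu(x)), relu(x))

    def test_softmax_symmetry(self):
        p = softmax([0.0, 0.0])
        assert (p.p_benign, p.p_malignant) == (0.5, 0.5)

    def test_softmax_overflow_safe(self):
        p = softmax([1000.0, 1000.0])
        assert (p.p_benign, p.p_malignant) == (0.5, 0.5)

    def test_softmax_closed_form(self):
        p = softmax([math.log(3.0), 0.0])
        assert p.p_benign == pytest.approx(0.75, abs=1e-12)
        assert p.p_malignant == pytest.approx(0.25, abs=1e-12)

    def test_softmax_shift_invariant(self, rng):
        z = rng.normal(size=2)
        a, b = softmax(z), softmax(z + 17.3)
        assert a.p_benign == pytest.approx(b.p_benign, abs=1e-12)


class TestCrossEntropy:
    def test_perfect_prediction_is_zero(self):
        labels = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert cross_entropy(labels, labels) == pytest.approx(0.0, abs=1e-10)

    def test_uniform_prediction_is_ln2(self):
        labels = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 0.0]])
        probs = np.full((3, 2), 0.5)
        assert cross_entropy(labels, probs) == pytest.approx(math.log(2))

    def test_hand_evaluated_case(self):
        labels = np.array([[1.0, 0.0], [0.0, 1.0]])
        probs = np.array([[0.9, 0.1], [0.2, 0.8]])
        expected = -(math.log(0.9) + math.log(0.8)) / 2
        assert cross_entropy(labels, probs) == pytest.approx(expected)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape mismatch"):
            cross_entropy(np.ones((2, 2)), np.ones((3, 2)))

    def test_nonnegative(self, rng):
        for _ in range(20):
            z = rng.normal(size=(5, 2))
            probs = np.exp(z) / np.exp(z).sum(axis=1, keepdims=True)
            labels = np.eye(2)[rng.integers(0, 2, 5)]
            assert cross_entropy(labels, probs) >= 0.0


class TestGradients:
    @pytest.mark.parametrize("hidden", [(7, 4), (3,)])
    def test_analytic_matches_finite_differences(self, rng, hidden):
        """Backpropagated gradients agree with central differences to 1e−5
        on random small instances."""
        d, n = 5, 12
        X = rng.normal(size=(n, d))
        Y = np.eye(2)[rng.integers(0, 2, n)]
        params = init_head(d, seed=3, hidden_sizes=hidden)
        gW, gb = head_gradients(params, X, Y)
        eps = 1e-6
        for arrs, grads in ((params.weights, gW), (params.biases, gb)):
            for arr, g in zip(arrs, grads):
                flat_idx = rng.choice(arr.size, size=min(20, arr.size),
                                      replace=False)
                for idx in flat_idx:
                    ij = np.unravel_index(idx, arr.shape)
                    orig = arr[ij]
                    arr[ij] = orig + eps
                    up = head_loss(params, X, Y)
                    arr[ij] = orig - eps
                    down = head_loss(params, X, Y)
                    arr[ij] = orig
                    numeric = (up - down) / (2 * eps)
                    assert numeric == pytest.approx(g[ij], abs=1e-5)


class TestAdam:
    def test_degenerates_to_rescaled_gradient_step(self):
        """With β₁ = β₂ = 0 and no bias correction, the update is
        lr · g / (|g| + ε)."""
        lr, eps = 0.01, 1e-8
        p = np.array([1.0, -2.0, 3.0])
        g = np.array([0.5, -0.25, 0.0])
        opt = _Adam([p.shape], lr, 0.0, 0.0, eps=eps, bias_correction=False)
        expected = p - lr * g / (np.abs(g) + eps)
        opt.step([p], [g])
        assert np.allclose(p, expected)

    def test_bias_correction_first_step_is_full_step(self):
        lr = 0.1
        p = np.array([0.0])
        g = np.array([2.0])
        opt = _Adam([p.shape], lr, 0.9, 0.999)
        opt.step([p], [g])
        # m̂ = g, v̂ = g² on step 1, so the step is −lr·g/(|g|+ε) ≈ −lr
        assert p[0] == pytest.approx(-lr, rel=1e-6)


def _blob_data(rng, n=200, d=8, gap=4.0):
    X = rng.normal(size=(n, d))
    y = np.array(["benign"] * (n // 2) + ["malignant"] * (n // 2))
    X[y == "malignant", 0] += gap
    return X, y


class TestHeadNetClassifier:
    def test_separable_blobs_converge(self, rng):
        """Two well-separated Gaussian blobs are fit to ≥95% training
        accuracy within 50 epochs and the loss decreases."""
        X, y = _blob_data(rng)
        clf = HeadNetClassifier(epochs=50, seed=0).fit(X, y)
        assert clf.loss_curve_[-1] < clf.loss_curve_[0]
        assert clf.score(X, y) >= 0.95

    def test_zero_epochs_returns_initialization(self, rng):
        X, y = _blob_data(rng, n=20)
        clf = HeadNetClassifier(hidden_sizes=(6, 3), epochs=0, seed=7).fit(X, y)
        ref = init_head(X.shape[1], 7, (6, 3))
        for W_fit, W_init in zip(clf.params_.weights, ref.weights):
            assert np.array_equal(W_fit, W_init)

    def test_deterministic_for_fixed_seed(self, rng):
        X, y = _blob_data(rng, n=60)
        a = HeadNetClassifier(hidden_sizes=(6, 3), epochs=5, seed=1).fit(X, y)
        b = HeadNetClassifier(hidden_sizes=(6, 3), epochs=5, seed=1).fit(X, y)
        for Wa, Wb in zip(a.params_.weights, b.params_.weights):
            assert np.array_equal(Wa, Wb)
        assert a.loss_curve_ == b.loss_curve_

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(10, 4))
        with pytest.raises(ValueError, match="single class"):
            HeadNetClassifier().fit(X, ["benign"] * 10)

    def test_dimension_mismatch_at_predict(self, rng):
        X, y = _blob_data(rng, n=20, d=8)
        clf = HeadNetClassifier(hidden_sizes=(4,), epochs=1, seed=0).fit(X, y)
        with pytest.raises(ValueError):
            clf.predict_proba(rng.normal(size=(3, 5)))

    def test_default_architecture_widths(self, rng):
        X, y = _blob_data(rng, n=40)
        clf = HeadNetClassifier(epochs=1, seed=0).fit(X, y)
        assert clf.params_.layer_widths == (1024, 512, 2)

    def test_probabilities_normalized(self, rng):
        X, y = _blob_data(rng, n=40)
        clf = HeadNetClassifier(hidden_sizes=(6, 3), epochs=3, seed=0).fit(X, y)
        P = clf.predict_proba(rng.normal(size=(25, 8)))
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-9)
        assert (P >= 0).all()

    def test_batch_equals_per_example(self, rng):
        X, y = _blob_data(rng, n=30)
        clf = HeadNetClassifier(hidden_sizes=(5, 3), epochs=2, seed=0).fit(X, y)
        Xq = rng.normal(size=(7, 8))
        batch = clf.predict_proba(Xq)
        single = np.vstack([clf.predict_proba(Xq[i:i + 1]) for i in range(7)])
        assert np.allclose(batch, single, atol=1e-12)

    def test_sklearn_clone_and_pipeline(self, rng):
        X, y = _blob_data(rng, n=60)
        clf = HeadNetClassifier(hidden_sizes=(16, 8), epochs=80,
                                batch_size=8, seed=0)
        assert clone(clf).get_params() == clf.get_params()
        pipe = make_pipeline(StandardScaler(), clone(clf)).fit(X, y)
        assert pipe.score(X, y) >= 0.9

    def test_early_stopping_shortens_training(self, rng):
        X, y = _blob_data(rng, n=60, gap=8.0)
        clf = HeadNetClassifier(
            hidden_sizes=(16, 8), epochs=300, early_stopping=True,
            patience=5, min_delta=1e-3, seed=0,
        ).fit(X, y)
        assert len(clf.loss_curve_) < 300


class TestForwardPass:
    def test_zero_head_is_uniform(self):
        params = HeadParams(
            weights=[np.zeros((3, 4)), np.zeros((4, 2))],
            biases=[np.zeros(4), np.zeros(2)],
        )
        fv = FeatureVector(np.array([1.0, -2.0, 0.5]), "p", (0, 0), Label.BENIGN)
        pair = predict_proba(params, fv)
        assert (pair.p_benign, pair.p_malignant) == (0.5, 0.5)

    def test_hand_computed_toy_forward(self):
        """d=2 head with hand-set weights matches manual evaluation."""
        params = HeadParams(
            weights=[np.array([[1.0, -1.0], [0.0, 2.0]]),
                     np.array([[1.0, 0.0], [1.0, -1.0]])],
            biases=[np.array([0.0, 1.0]), np.array([0.0, 0.0])],
        )
        x = np.array([2.0, 1.0])
        # layer 1: z = [2, -2+2+1] = [2, 1] → relu [2, 1]
        # layer 2 logits: [2+1, -1] = [3, -1]
        e = np.exp([3.0, -1.0])
        expected = e / e.sum()
        fv = FeatureVector(x, "p", (0, 0), Label.BENIGN)
        pair = predict_proba(params, fv)
        assert pair.p_benign == pytest.approx(expected[0], abs=1e-12)
        assert pair.p_malignant == pytest.approx(expected[1], abs=1e-12)


class TestFunctionalWrappers:
    def _features(self, rng, n=40, d=6):
        X, y = _blob_data(rng, n=n, d=d)
        return [
            FeatureVector(X[i], f"img{i}", (0, 0), Label(y[i]))
            for i in range(n)
        ]

    def test_train_head_and_predict(self, rng):
        feats = self._features(rng)
        config = TrainConfig(epochs=20, seed=0, hidden_sizes=(8, 4))
        params, history = train_head(feats, config)
        assert len(history) >= 1 and history[-1] < history[0]
        probs = predict_proba_batch(params, feats)
        assert probs.shape == (len(feats), 2)

    def test_checkpoint_round_trip(self, rng, tmp_path):
        feats = self._features(rng, n=20)
        config = TrainConfig(epochs=2, seed=0, hidden_sizes=(5, 3))
        params, history = train_head(feats, config)
        path = tmp_path / "head.ckpt.npz"
        save_head(path, params, config=config, loss_history=history)
        loaded = load_head(path)
        for Wa, Wb in zip(params.weights, loaded.weights):
            assert np.array_equal(Wa, Wb)
        assert path.with_suffix(".npz.json").exists()

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(learning_rate=-1.0)
        with pytest.raises(ValueError):
            TrainConfig(beta1=1.0)
        with pytest.raises(ValueError):
            TrainConfig(batch_size=0)
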