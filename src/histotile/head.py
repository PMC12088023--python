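"""The trainable fully connected classification head.

A three-layer fully connected network, d → 1024 → 512 → 2, with ReLU on the
two hidden layers and a softmax output, trained on frozen backbone features
with the cross-entropy loss

    L = −(1/S) Σ_i Σ_j y_ij log p_ij

by adaptive-moment (Adam) gradient descent with bias correction
(learning rate 0.001, momentum factors 0.9/0.999, batch size 32 by
default). Only the head's parameters change during training — the backbone
stays frozen.

:class:`HeadNetClassifier` is a scikit-learn estimator (fit /
predict_proba / predict, ``get_params``/``set_params``, fitted attributes
with trailing underscores) and composes with sklearn pipelines and model
selection. The module-level operations (:func:`relu`, :func:`softmax`,
:func:`cross_entropy`, :func:`init_head`, :func:`train_head`,
:func:`predict_proba`) are thin functional entry points over the same
implementation; analytic gradients are exposed for finite-difference
verification.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .backbone import FeatureVector
from .types import HeadParams, Label, ProbabilityPair

CE_EPS = 1e-12
DEFAULT_HIDDEN = (1024, 512)


def relu(x: np.ndarray) -> np.ndarray:
    """Elementwise max(x, 0)."""
    return np.maximum(np.asarray(x, dtype=np.float64), 0.0)


def softmax(z: np.ndarray) -> ProbabilityPair:
    """Softmax over a length-2 logit vector, overflow-safe.

    Computed with max-subtraction so shift invariance holds exactly:
    softmax(z + c) = softmax(z) for any scalar c.
    """
    z = np.asarray(z, dtype=np.float64)
    if z.shape != (2,):
        raise ValueError(f"expected a length-2 logit vector, got shape {z.shape}")
    p = softmax_rows(z[np.newaxis])[0]
    return ProbabilityPair(p[0], p[1])


def softmax_rows(Z: np.ndarray) -> np.ndarray:
    """Row-wise softmax with max-subtraction."""
    Z = np.asarray(Z, dtype=np.float64)
    e = np.exp(Z - Z.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(labels: np.ndarray, probs: np.ndarray) -> float:
    """Mean cross-entropy between one-hot labels and predicted rows.

    Probabilities are clipped to [ε, 1−ε] (ε = 1e−12) before the log, so
    the loss is finite, nonnegative and zero (up to ε) only for exact
    predictions.
    """
    labels = np.asarray(labels, dtype=np.float64)
    probs = np.asarray(probs, dtype=np.float64)
    if labels.shape != probs.shape:
        raise ValueError(
            f"shape mismatch: labels {labels.shape} vs probs {probs.shape}"
        )
    clipped = np.clip(probs, CE_EPS, 1.0 - CE_EPS)
    return float(-(labels * np.log(clipped)).sum() / labels.shape[0])


@dataclass
class TrainConfig:
    """Training hyperparameters for the head.

    Defaults follow the reference configuration: Adam with learning rate
    0.001, momentum factors β₁ = 0.9 and β₂ = 0.999, batch size 32. The
    epoch budget and early stopping (on a training-loss plateau) are
    artifact choices, configurable here.
    """

    learning_rate: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    batch_size: int = 32
    epochs: int = 100
    seed: int = 0
    early_stopping: bool = True
    patience: int = 10
    min_delta: float = 1e-4
    hidden_sizes: Tuple[int, ...] = DEFAULT_HIDDEN

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not (0 <= self.beta1 < 1 and 0 <= self.beta2 < 1):
            raise ValueError("momentum factors must lie in [0, 1)")
        if self.batch_size < 1:
            raise ValueError("batch_size must be ≥ 1")


def init_head(
    input_dim: int,
    seed: int,
    hidden_sizes: Sequence[int] = DEFAULT_HIDDEN,
    n_classes: int = 2,
) -> HeadParams:
    """Variance-preserving (He) random initialization, reproducible by seed."""
    rng = np.random.default_rng(seed)
    widths = [int(input_dim), *[int(h) for h in hidden_sizes], int(n_classes)]
    weights, biases = [], []
    for d_in, d_out in zip(widths[:-1], widths[1:]):
        weights.append(rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_in, d_out)))
        biases.append(np.zeros(d_out))
    return HeadParams(weights=weights, biases=biases)


def _forward(params: HeadParams, X: np.ndarray):
    """Forward pass returning probabilities and per-layer activations."""
    activations = [X]
    a = X
    n_layers = len(params.weights)
    for k, (W, b) in enumerate(zip(params.weights, params.biases)):
        z = a @ W + b
        a = relu(z) if k < n_layers - 1 else z
        activations.append(a)
    return softmax_rows(activations[-1]), activations


def head_loss(params: HeadParams, X: np.ndarray, Y: np.ndarray) -> float:
    """Cross-entropy loss of the head on one-hot targets Y."""
    probs, _ = _forward(params, X)
    return cross_entropy(Y, probs)


def head_gradients(params: HeadParams, X: np.ndarray, Y: np.ndarray):
    """Analytic gradients of the cross-entropy loss w.r.t. every parameter.

    Returns (grad_weights, grad_biases) matching the shapes in ``params``.
    Softmax and cross-entropy combine to the standard output-layer error
    (p − y)/S; hidden layers backpropagate through the ReLU mask.
    """
    S = X.shape[0]
    probs, acts = _forward(params, X)
    delta = (probs - Y) / S
    gW: List[np.ndarray] = [None] * len(params.weights)  # type: ignore
    gb: List[np.ndarray] = [None] * len(params.biases)  # type: ignore
    for k in range(len(params.weights) - 1, -1, -1):
        gW[k] = acts[k].T @ delta
        gb[k] = delta.sum(axis=0)
        if k > 0:
            delta = (delta @ params.weights[k].T) * (acts[k] > 0)
    return gW, gb


class _Adam:
    """Adaptive-moment estimation with bias correction.

    With β₁ = β₂ = 0 and bias correction off, the update degenerates to the
    rescaled gradient step lr · g / (|g| + ε).
    """

    def __init__(self, shapes, lr, beta1, beta2, eps=1e-8, bias_correction=True):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.bias_correction = bias_correction
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0

    def step(self, params: List[np.ndarray], grads: List[np.ndarray]) -> None:
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            if self.bias_correction:
                m_hat = self.m[i] / (1 - self.beta1 ** self.t)
                v_hat = self.v[i] / (1 - self.beta2 ** self.t)
            else:
                m_hat, v_hat = self.m[i], self.v[i]
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


class HeadNetClassifier(ClassifierMixin, BaseEstimator):
    """Fully connected softmax classifier trained with Adam.

    Parameters
    ----------
    hidden_sizes : tuple of int, default (1024, 512)
        Hidden-layer widths; the canonical head is d → 1024 → 512 → 2.
    learning_rate, beta1, beta2, batch_size
        Adam hyperparameters (defaults 0.001, 0.9, 0.999, 32).
    epochs : int, default 100
        Maximum training epochs; ``epochs=0`` leaves the random
        initialization untouched.
    early_stopping : bool, default True
        Stop when the epoch-mean training loss fails to improve by
        ``min_delta`` for ``patience`` consecutive epochs.
    seed : int, default 0
        Seeds initialization and the per-epoch shuffles; identical data and
        seed give identical fitted parameters.

    Attributes
    ----------
    classes_ : ndarray of shape (2,)
    params_ : HeadParams
        Fitted weights and biases.
    loss_curve_ : list of float
        Per-epoch mean training loss.
    n_features_in_ : int
    """

    def __init__(
        self,
        hidden_sizes: Tuple[int, ...] = DEFAULT_HIDDEN,
        learning_rate: float = 0.001,
        beta1: float = 0.9,
        beta2: float = 0.999,
        batch_size: int = 32,
        epochs: int = 100,
        early_stopping: bool = True,
        patience: int = 10,
        min_delta: float = 1e-4,
        seed: int = 0,
    ):
        self.hidden_sizes = hidden_sizes
        self.learning_rate = learning_rate
        self.beta1 = beta1
        self.beta2 = beta2
        self.batch_size = batch_size
        self.epochs = epochs
        self.early_stopping = early_stopping
        self.patience = patience
        self.min_delta = min_delta
        self.seed = seed

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=np.float64)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError(
                "training set contains a single class; need both classes"
            )
        if len(self.classes_) > 2:
            raise ValueError("binary classifier: more than two classes found")
        # hyperparameter validation via TrainConfig invariants
        TrainConfig(
            learning_rate=self.learning_rate, beta1=self.beta1,
            beta2=self.beta2, batch_size=self.batch_size,
        )
        self.n_features_in_ = X.shape[1]
        n, k = X.shape[0], len(self.classes_)
        Y = np.zeros((n, k))
        Y[np.arange(n), y_idx] = 1.0

        params = init_head(self.n_features_in_, self.seed, self.hidden_sizes, k)
        flat = list(params.weights) + list(params.biases)
        opt = _Adam(
            [p.shape for p in flat], self.learning_rate, self.beta1, self.beta2
        )
        rng = np.random.default_rng(np.random.SeedSequence([self.seed & 0x7FFFFFFF, 1]))
        self.loss_curve_ = []
        best, stall = np.inf, 0
        nw = len(params.weights)
        for _epoch in range(self.epochs):
            order = rng.permutation(n)
            batch_losses = []
            for start in range(0, n, self.batch_size):  # last partial batch kept
                idx = order[start:start + self.batch_size]
                Xb, Yb = X[idx], Y[idx]
                probs, _ = _forward(params, Xb)
                batch_losses.append(cross_entropy(Yb, probs))
                gW, gb = head_gradients(params, Xb, Yb)
                opt.step(flat, list(gW) + list(gb))
                params = HeadParams(weights=flat[:nw], biases=flat[nw:])
            epoch_loss = float(np.mean(batch_losses))
            self.loss_curve_.append(epoch_loss)
            if self.early_stopping:
                if epoch_loss < best - self.min_delta:
                    best, stall = epoch_loss, 0
                else:
                    stall += 1
                    if stall >= self.patience:
                        break
        self.params_ = params
        return self

    def decision_logits(self, X) -> np.ndarray:
        check_is_fitted(self, "params_")
        X = check_array(X, dtype=np.float64)
        _, acts = _forward(self.params_, X)
        return acts[-1]

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "params_")
        X = check_array(X, dtype=np.float64)
        probs, _ = _forward(self.params_, X)
        return probs

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


# ---------------------------------------------------------------------------
# functional wrappers over FeatureVector collections


def _feature_matrix(features: Sequence[FeatureVector]):
    X = np.stack([f.values for f in features])
    y = np.array([f.label.value for f in features])
    return X, y


def train_head(
    features: Sequence[FeatureVector], config: TrainConfig
) -> Tuple[HeadParams, List[float]]:
    """Train the head on labeled feature vectors; returns fitted parameters
    and the per-epoch mean loss history.

    Requires at least one example of each class and a common feature
    dimension. Reproducible for a fixed seed and data order; the backbone
    that produced the features is untouched.
    """
    X, y = _feature_matrix(features)
    clf = HeadNetClassifier(
        hidden_sizes=config.hidden_sizes,
        learning_rate=config.learning_rate,
        beta1=config.beta1,
        beta2=config.beta2,
        batch_size=config.batch_size,
        epochs=config.epochs,
        early_stopping=config.early_stopping,
        patience=config.patience,
        min_delta=config.min_delta,
        seed=config.seed,
    ).fit(X, y)
    return clf.params_, clf.loss_curve_


def predict_proba(head: HeadParams, feature: FeatureVector) -> ProbabilityPair:
    """Class probabilities for one feature vector: softmax over the head's
    forward pass, with index 0 = benign, 1 = malignant."""
    probs, _ = _forward(head, feature.values[np.newaxis])
    return ProbabilityPair(probs[0, 0], probs[0, 1])


def predict_proba_batch(head: HeadParams, features: Sequence[FeatureVector]) -> np.ndarray:
    """Vectorized counterpart of :func:`predict_proba`, order-preserving."""
    X = np.stack([f.values for f in features])
    probs, _ = _forward(head, X)
    return probs


# ---------------------------------------------------------------------------
# checkpoint serialization


def save_head(path, params: HeadParams, config: Optional[TrainConfig] = None,
              loss_history: Optional[Sequence[float]] = None) -> None:
    """Serialize a head checkpoint (portable archive + JSON sidecar)."""
    path = Path(path)
    arrays = {}
    for i, (W, b) in enumerate(zip(params.weights, params.biases)):
        arrays[f"W{i}"] = W
        arrays[f"b{i}"] = b
    np.savez(path, n_layers=np.array(len(params.weights)), **arrays)
    sidecar = {
        "input_dim": params.input_dim,
        "layer_widths": list(params.layer_widths),
        "config": vars(config) if config else None,
        "loss_history": list(map(float, loss_history or [])),
    }
    if sidecar["config"] is not None:
        sidecar["config"] = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in sidecar["config"].items()
        }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def load_head(path) -> HeadParams:
    """Load a head checkpoint written by :func:`save_head`."""
    path = Path(path)
    if not path.exists() and path.with_suffix(path.suffix + ".npz").exists():
        path = path.with_suffix(path.suffix + ".npz")
    with np.load(path) as data:
        n = int(data["n_layers"])
        weights = [data[f"W{i}"] for i in range(n)]
        biases = [data[f"b{i}"] for i in range(n)]
    return HeadParams(weights=weights, biases=biases)
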