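"""Single-hidden-layer logistic network trained by online gradient descent.

The meta-learner is deliberately small and classical: M inputs (one per
base predictor after preprocessing), H logistic hidden units (default
20; 5-60 is the explored range), one logistic output unit read against a
0.5 decision threshold.  Training is plain per-sample gradient descent
over shuffled epochs with early stopping monitored on a held-out test
fold: when the test-fold accuracy has not exceeded its running maximum
for ``patience`` consecutive epochs (default 100) training stops and the
weight snapshot from the best epoch is returned.

Every source of randomness (weight init, per-epoch shuffles) flows from
one seeded generator, so identical configs and data reproduce training
bit-for-bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import DivergenceError
from .preprocess import FeatureMatrix


def sigmoid(z):
    """Numerically safe logistic function."""
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500.0, 500.0)))


@dataclass
class AnnConfig:
    """Hyperparameters of the meta-learner.

    The published architecture fixes topology (M inputs, logistic
    activations, one output, 0.5 threshold, 20 hidden units, 100-epoch
    patience); learning rate, epoch cap, init scale and loss are
    unreported there and are plain config surface here.
    """

    n_inputs: int
    n_hidden: int = 20
    learning_rate: float = 0.1
    max_epochs: int = 500
    patience: int = 100
    init_scale: float = 0.5
    seed: int = 0
    loss: str = "mse"

    def __post_init__(self) -> None:
        if self.n_inputs < 1 or self.n_hidden < 1:
            raise ValueError("network dimensions must be positive")
        if self.learning_rate <= 0 or self.init_scale < 0:
            raise ValueError("learning_rate must be > 0 and init_scale >= 0")
        if self.patience < 1 or self.max_epochs < 1:
            raise ValueError("patience and max_epochs must be >= 1")
        if self.loss not in ("mse", "log-loss"):
            raise ValueError(f"unknown loss {self.loss!r}")
        if not 5 <= self.n_hidden <= 60:
            warnings.warn(
                f"n_hidden={self.n_hidden} outside the explored range [5, 60]",
                stacklevel=2,
            )


@dataclass
class AnnModel:
    """Weights of an M -> H -> 1 logistic network."""

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: float
    threshold: float = 0.5

    def copy(self) -> "AnnModel":
        return AnnModel(self.W1.copy(), self.b1.copy(), self.W2.copy(),
                        float(self.b2), self.threshold)


@dataclass
class TrainHistory:
    """Per-epoch record of training loss and test-fold accuracy."""

    train_loss: list[float] = field(default_factory=list)
    test_acc: list[float] = field(default_factory=list)
    best_epoch: int = 0
    stopped_reason: str = ""

    @property
    def n_epochs(self) -> int:
        return len(self.train_loss)


def _init_from_rng(rng: np.random.Generator, config: AnnConfig) -> AnnModel:
    s = config.init_scale
    W1 = rng.uniform(-s, s, size=(config.n_hidden, config.n_inputs))
    W2 = rng.uniform(-s, s, size=config.n_hidden)
    return AnnModel(W1=W1, b1=np.zeros(config.n_hidden), W2=W2, b2=0.0)


def init_model(config: AnnConfig) -> AnnModel:
    """Seeded uniform weight init on [-init_scale, +init_scale]; zero biases."""
    return _init_from_rng(np.random.default_rng(config.seed), config)


def forward(model: AnnModel, x: np.ndarray) -> float:
    """Network output sigma(W2 . sigma(W1 x + b1) + b2), strictly in (0, 1)."""
    x = np.asarray(x, dtype=float)
    if x.shape != (model.W1.shape[1],):
        raise ValueError(f"expected input of length {model.W1.shape[1]}, got {x.shape}")
    a1 = sigmoid(model.W1 @ x + model.b1)
    return float(sigmoid(model.W2 @ a1 + model.b2))


def forward_batch(model: AnnModel, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    a1 = sigmoid(X @ model.W1.T + model.b1)
    return sigmoid(a1 @ model.W2 + model.b2)


def classify(score, threshold: float = 0.5):
    """Map network output(s) to +/-1 calls; scores >= threshold are positive."""
    arr = np.asarray(score, dtype=float)
    calls = np.where(arr >= threshold, 1, -1)
    return int(calls) if arr.ndim == 0 else calls


def sample_loss(model: AnnModel, x: np.ndarray, target: float, loss: str = "mse") -> float:
    """Loss of one sample; target is in {0, 1}."""
    y = forward(model, x)
    if loss == "mse":
        return 0.5 * (y - target) ** 2
    eps = 1e-12
    return -(target * np.log(y + eps) + (1.0 - target) * np.log(1.0 - y + eps))


def sample_gradients(model: AnnModel, x: np.ndarray, target: float,
                     loss: str = "mse") -> dict[str, np.ndarray]:
    """Backpropagated gradients of ``sample_loss`` w.r.t. all weights."""
    x = np.asarray(x, dtype=float)
    z1 = model.W1 @ x + model.b1
    a1 = sigmoid(z1)
    y = float(sigmoid(model.W2 @ a1 + model.b2))
    if loss == "mse":
        delta2 = (y - target) * y * (1.0 - y)
    else:
        delta2 = y - target
    delta1 = model.W2 * delta2 * a1 * (1.0 - a1)
    return {
        "W1": delta1[:, None] * x[None, :],
        "b1": delta1,
        "W2": delta2 * a1,
        "b2": np.asarray(delta2),
    }


def accuracy(model: AnnModel, fm: FeatureMatrix) -> float:
    calls = classify(forward_batch(model, fm.X), model.threshold)
    return float(np.mean(calls == fm.labels))


def train(config: AnnConfig, train_fm: FeatureMatrix,
          test_fm: FeatureMatrix) -> tuple[AnnModel, TrainHistory]:
    """Online gradient descent with test-fold early stopping.

    Each epoch visits every training sample once in a fresh shuffled
    order, updating weights per sample; after the epoch the accuracy on
    *test_fm* is recorded.  Training stops once that accuracy has failed
    to exceed its running maximum for ``config.patience`` consecutive
    epochs, or at ``config.max_epochs``.  The returned model is the
    snapshot from the best epoch (earliest epoch on ties).
    """
    if train_fm.X.shape[0] == 0 or test_fm.X.shape[0] == 0:
        raise ValueError("train and test sets must be non-empty")
    if train_fm.X.shape[1] != config.n_inputs or test_fm.X.shape[1] != config.n_inputs:
        raise ValueError("feature width does not match config.n_inputs")
    rng = np.random.default_rng(config.seed)
    model = _init_from_rng(rng, config)
    Xtr = np.ascontiguousarray(train_fm.X)
    targets = (train_fm.labels.astype(float) + 1.0) / 2.0  # +/-1 -> 1/0
    n = Xtr.shape[0]
    lr = config.learning_rate
    use_mse = config.loss == "mse"
    W1, b1, W2 = model.W1, model.b1, model.W2
    b2 = model.b2
    history = TrainHistory()
    best_acc = -np.inf
    best_model = model.copy()
    since_best = 0
    eps = 1e-12
    for epoch in range(1, config.max_epochs + 1):
        perm = rng.permutation(n)
        total = 0.0
        for i in perm:
            x = Xtr[i]
            t = targets[i]
            a1 = sigmoid(W1 @ x + b1)
            y = float(sigmoid(W2 @ a1 + b2))
            if use_mse:
                total += 0.5 * (y - t) ** 2
                delta2 = (y - t) * y * (1.0 - y)
            else:
                total += -(t * np.log(y + eps) + (1.0 - t) * np.log(1.0 - y + eps))
                delta2 = y - t
            delta1 = W2 * (delta2 * a1 * (1.0 - a1))
            W2 -= (lr * delta2) * a1
            b2 -= lr * delta2
            W1 -= lr * delta1[:, None] * x[None, :]
            b1 -= lr * delta1
        model.b2 = b2
        mean_loss = total / n
        if not np.isfinite(mean_loss):
            raise DivergenceError(f"non-finite training loss at epoch {epoch}")
        acc = accuracy(model, test_fm)
        history.train_loss.append(mean_loss)
        history.test_acc.append(acc)
        if acc > best_acc:
            best_acc = acc
            history.best_epoch = epoch
            best_model = model.copy()
            since_best = 0
        else:
            since_best += 1
        if since_best >= config.patience:
            history.stopped_reason = "patience"
            break
    else:
        history.stopped_reason = "max_epochs"
    return best_model, history


def model_to_dict(model: AnnModel) -> dict:
    return {
        "W1": model.W1.tolist(),
        "b1": model.b1.tolist(),
        "W2": model.W2.tolist(),
        "b2": float(model.b2),
        "threshold": model.threshold,
    }


def model_from_dict(d: dict) -> AnnModel:
    return AnnModel(
        W1=np.asarray(d["W1"], dtype=float),
        b1=np.asarray(d["b1"], dtype=float),
        W2=np.asarray(d["W2"], dtype=float),
        b2=float(d["b2"]),
        threshold=float(d.get("threshold", 0.5)),
    )
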