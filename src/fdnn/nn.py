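"""Fully-connected softmax head trained on cross-entropy.

A small multilayer perceptron: ReLU hidden layers, a two-unit softmax
output, mini-batch Adam on the mean binary cross-entropy.  It consumes
either the flattened one-hot tree-vote tensor (input width 2M) or a raw
standardized expression matrix (input width p, for the plain-DNN
baselines).  Forward, backward and the optimizer are implemented
directly in NumPy — the network is tiny, so there is no need for an
autodiff framework, and explicit code keeps the gradient check honest.

The first-layer weights also drive the Connection Weights importance:
the score of input unit j is the sum of absolute weights leaving it,
and for one-hot tree inputs the two channels of a tree are pooled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DNNHead",
    "TrainConfig",
    "relu",
    "softmax_prob",
    "softmax",
    "cross_entropy_loss",
]

_PROB_CLAMP = 1e-12


def relu(x):
    """Rectified linear unit, elementwise max(x, 0)."""
    return np.maximum(x, 0)


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax with the usual max-shift for stability."""
    shifted = logits - logits.max(axis=-1, keepdims=True)
    exp = np.exp(shifted)
    return exp / exp.sum(axis=-1, keepdims=True)


def softmax_prob(mu0, mu1):
    """Two-class softmax probability of class 1, stable for large logits."""
    mu0 = np.asarray(mu0, dtype=float)
    mu1 = np.asarray(mu1, dtype=float)
    shift = np.maximum(mu0, mu1)
    e0 = np.exp(mu0 - shift)
    e1 = np.exp(mu1 - shift)
    return e1 / (e0 + e1)


def cross_entropy_loss(p_hat: np.ndarray, y: np.ndarray) -> float:
    """Mean binary cross-entropy, with probabilities clamped away from 0/1."""
    p_hat = np.asarray(p_hat, dtype=float)
    y = np.asarray(y, dtype=float)
    if p_hat.shape != y.shape:
        raise ValueError(f"shape mismatch: p_hat {p_hat.shape} vs y {y.shape}")
    p = np.clip(p_hat, _PROB_CLAMP, 1 - _PROB_CLAMP)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


@dataclass
class TrainConfig:
    """Optimization settings for the head (Adam on mini-batches)."""

    learning_rate: float = 1e-3
    batch_size: int = 64
    epochs: int = 200
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    patience: int = 25          # early stop after this many epochs w/o improvement
    min_delta: float = 1e-4     # improvement smaller than this does not count
    weight_decay: float = 0.0   # L2 penalty on weights (not biases); off by default
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning rate must be nonnegative")
        if self.batch_size < 1:
            raise ValueError("batch size must be >= 1")


class DNNHead:
    """ReLU MLP with a two-unit softmax output.

    ``layer_sizes`` runs from the input width to the output width, e.g.
    ``(600, 256, 64, 16, 2)`` for a 300-tree one-hot input.  The output
    width must be 2 (binary classification).  Layer widths conventionally
    decrease from the input; a violation is tolerated with a warning.
    """

    def __init__(self, layer_sizes: tuple[int, ...], seed: int | None = None):
        layer_sizes = tuple(int(s) for s in layer_sizes)
        if len(layer_sizes) < 2:
            raise ValueError("need at least input and output layer sizes")
        if layer_sizes[-1] != 2:
            raise ValueError(f"output layer must have 2 units, got {layer_sizes[-1]}")
        if any(s < 1 for s in layer_sizes):
            raise ValueError("all layer sizes must be positive")
        if list(layer_sizes[:-1]) != sorted(layer_sizes[:-1], reverse=True):
            import warnings

            warnings.warn(
                "hidden layer sizes do not decrease from the input; "
                "this deviates from the usual funnel architecture",
                stacklevel=2,
            )
        self.layer_sizes = layer_sizes
        self.seed = seed
        self._init_parameters(np.random.default_rng(seed))
        self.fitted = False
        self.loss_trace_: list[float] = []

    def _init_parameters(self, rng: np.random.Generator) -> None:
        # He-uniform: limit sqrt(6 / fan_in), suited to ReLU layers
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in zip(self.layer_sizes[:-1], self.layer_sizes[1:]):
            limit = np.sqrt(6.0 / fan_in)
            self.weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))

    # ------------------------------------------------------------------
    # forward / backward

    def _prepare_input(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 3 and X.shape[-1] == 2:
            X = X.reshape(X.shape[0], -1)  # channel-major flattening per tree
        if X.ndim != 2:
            raise ValueError(f"expected 2-d input (or n x M x 2 tensor), got {X.shape}")
        if X.shape[1] != self.layer_sizes[0]:
            raise ValueError(
                f"input width {X.shape[1]} does not match head input size "
                f"{self.layer_sizes[0]}"
            )
        return X

    def _forward_pass(self, X: np.ndarray) -> tuple[list[np.ndarray], np.ndarray]:
        """Returns (activations per layer incl. input, output probabilities)."""
        activations = [X]
        a = X
        last = len(self.weights) - 1
        for k, (W, b) in enumerate(zip(self.weights, self.biases)):
            z = a @ W + b
            a = z if k == last else relu(z)
            activations.append(a)
        return activations, softmax(activations[-1])

    def forward(self, X: np.ndarray) -> np.ndarray:
        """Per-sample class probabilities, shape (n, 2); rows sum to 1."""
        X = self._prepare_input(X)
        _, probs = self._forward_pass(X)
        return probs

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Class-1 probability per sample."""
        return self.forward(X)[:, 1]

    def _backward_pass(
        self, activations: list[np.ndarray], probs: np.ndarray, y: np.ndarray
    ) -> tuple[list[np.ndarray], list[np.ndarray]]:
        """Gradients of mean cross-entropy w.r.t. all weights and biases."""
        n = probs.shape[0]
        y_onehot = np.zeros_like(probs)
        y_onehot[np.arange(n), y.astype(int)] = 1.0
        delta = (probs - y_onehot) / n  # softmax + CE gradient at the logits
        grads_W: list[np.ndarray] = [None] * len(self.weights)
        grads_b: list[np.ndarray] = [None] * len(self.biases)
        for k in range(len(self.weights) - 1, -1, -1):
            grads_W[k] = activations[k].T @ delta
            grads_b[k] = delta.sum(axis=0)
            if k > 0:
                delta = (delta @ self.weights[k].T) * (activations[k] > 0)
        return grads_W, grads_b

    def loss_and_gradients(self, X: np.ndarray, y: np.ndarray):
        """Convenience hook used by the finite-difference gradient check."""
        X = self._prepare_input(X)
        activations, probs = self._forward_pass(X)
        loss = cross_entropy_loss(probs[:, 1], y)
        grads_W, grads_b = self._backward_pass(activations, probs, y)
        return loss, grads_W, grads_b

    # ------------------------------------------------------------------
    # training

    def train(self, X: np.ndarray, y: np.ndarray, config: TrainConfig | None = None):
        """Mini-batch Adam on the cross-entropy; returns the per-epoch loss trace."""
        config = config or TrainConfig()
        X = self._prepare_input(X)
        y = np.asarray(y).astype(int)
        if set(np.unique(y)) != {0, 1}:
            raise ValueError("training labels must contain both classes")
        n = X.shape[0]
        batch = min(config.batch_size, n)
        rng = np.random.default_rng(config.seed)

        m_W = [np.zeros_like(W) for W in self.weights]
        v_W = [np.zeros_like(W) for W in self.weights]
        m_b = [np.zeros_like(b) for b in self.biases]
        v_b = [np.zeros_like(b) for b in self.biases]
        step = 0
        best = np.inf
        stale = 0
        self.loss_trace_ = []

        for _epoch in range(config.epochs):
            order = rng.permutation(n)
            for start in range(0, n, batch):
                idx = order[start : start + batch]
                activations, probs = self._forward_pass(X[idx])
                grads_W, grads_b = self._backward_pass(activations, probs, y[idx])
                if config.weight_decay > 0:
                    for k in range(len(grads_W)):
                        grads_W[k] = grads_W[k] + config.weight_decay * self.weights[k]
                step += 1
                self._adam_update(grads_W, grads_b, m_W, v_W, m_b, v_b, step, config)
            epoch_loss = cross_entropy_loss(self.forward(X)[:, 1], y)
            if not np.isfinite(epoch_loss):
                raise FloatingPointError(
                    f"training loss became non-finite at epoch {_epoch}"
                )
            self.loss_trace_.append(epoch_loss)
            if epoch_loss < best - config.min_delta:
                best = epoch_loss
                stale = 0
            else:
                stale += 1
                if stale >= config.patience:
                    break
        self.fitted = True
        return self.loss_trace_

    def _adam_update(self, grads_W, grads_b, m_W, v_W, m_b, v_b, step, cfg):
        lr_t = cfg.learning_rate * np.sqrt(1 - cfg.beta2**step) / (1 - cfg.beta1**step)
        for k in range(len(self.weights)):
            for param, grad, m, v in (
                (self.weights[k], grads_W[k], m_W[k], v_W[k]),
                (self.biases[k], grads_b[k], m_b[k], v_b[k]),
            ):
                m *= cfg.beta1
                m += (1 - cfg.beta1) * grad
                v *= cfg.beta2
                v += (1 - cfg.beta2) * grad**2
                param -= lr_t * m / (np.sqrt(v) + cfg.eps)

    # ------------------------------------------------------------------
    # importance

    def connection_weight_importance(self, pooled_channels: bool = True) -> np.ndarray:
        """Connection Weights importance of each input unit.

        Sums absolute first-layer weights per input unit.  With
        ``pooled_channels`` (the default, for one-hot tree inputs of width
        2M) the two channels of each tree are added, giving a length-M
        vector; otherwise a score per raw input column is returned.
        """
        if not self.fitted:
            raise RuntimeError("head is not fitted; train it before computing importance")
        raw = np.abs(self.weights[0]).sum(axis=1)
        if pooled_channels:
            if raw.size % 2 != 0:
                raise ValueError("input width is odd; cannot pool one-hot channels")
            raw = raw.reshape(-1, 2).sum(axis=1)
        return raw

    # ------------------------------------------------------------------
    # (de)serialization

    def to_dict(self) -> dict:
        return {
            "format": "fdnn-head-v1",
            "layer_sizes": list(self.layer_sizes),
            "weights": [W.tolist() for W in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "fitted": self.fitted,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "DNNHead":
        if payload.get("format") != "fdnn-head-v1":
            raise ValueError("unrecognized head bundle format")
        head = cls(tuple(payload["layer_sizes"]))
        head.weights = [np.asarray(W, dtype=float) for W in payload["weights"]]
        head.biases = [np.asarray(b, dtype=float) for b in payload["biases"]]
        head.fitted = bool(payload["fitted"])
        return head


def normalize_importance(v: np.ndarray) -> np.ndarray:
    """Scale a nonnegative score vector to sum to one."""
    v = np.asarray(v, dtype=float)
    total = v.sum()
    if total <= 0:
        return np.full_like(v, 1.0 / v.size)
    return v / total
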