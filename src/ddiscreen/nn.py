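"""Seeded feed-forward multi-label network, written directly on numpy.

The classifier maps a pair-feature vector to independent per-type
probabilities (sigmoid outputs, one per DDI type).  It is deliberately
small and fully deterministic: identical data, configuration and seed
produce bit-identical weights, which the model bundle format relies on.

Training minimizes per-type binary cross-entropy with optional positive
weighting (to counter the heavy negative imbalance across 113 types),
using Adam with mini-batches and early stopping on a held-out
validation split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def _softplus(x: np.ndarray) -> np.ndarray:
    # stable log(1 + exp(x))
    return np.maximum(x, 0.0) + np.log1p(np.exp(-np.abs(x)))


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class MLPParams:
    """Weight matrices and biases, one pair per layer."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]

    def copy(self) -> "MLPParams":
        return MLPParams([w.copy() for w in self.weights], [b.copy() for b in self.biases])

    def to_flat(self) -> np.ndarray:
        parts = []
        for w, b in zip(self.weights, self.biases):
            parts.append(w.ravel())
            parts.append(b.ravel())
        return np.concatenate(parts)

    @staticmethod
    def from_flat(flat: np.ndarray, layer_sizes: list[int]) -> "MLPParams":
        weights, biases, pos = [], [], 0
        for fan_in, fan_out in zip(layer_sizes[:-1], layer_sizes[1:]):
            w = flat[pos : pos + fan_in * fan_out].reshape(fan_in, fan_out)
            pos += fan_in * fan_out
            b = flat[pos : pos + fan_out]
            pos += fan_out
            weights.append(w.copy())
            biases.append(b.copy())
        return MLPParams(weights, biases)


def init_params(layer_sizes: list[int], rng: np.random.Generator) -> MLPParams:
    """He-normal initialization, seeded."""
    weights, biases = [], []
    for fan_in, fan_out in zip(layer_sizes[:-1], layer_sizes[1:]):
        scale = np.sqrt(2.0 / fan_in)
        weights.append(rng.normal(0.0, scale, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return MLPParams(weights, biases)


def forward_logits(params: MLPParams, X: np.ndarray) -> np.ndarray:
    """Logits of the output layer; hidden layers use rectified activations."""
    h = X
    n_layers = len(params.weights)
    for i, (w, b) in enumerate(zip(params.weights, params.biases)):
        h = h @ w + b
        if i < n_layers - 1:
            h = np.maximum(h, 0.0)
    return h


def predict_proba(params: MLPParams, X: np.ndarray) -> np.ndarray:
    return sigmoid(forward_logits(params, X))


def weighted_bce_loss(
    logits: np.ndarray, Y: np.ndarray, pos_weight: np.ndarray
) -> float:
    """Mean weighted binary cross-entropy computed from logits (stable)."""
    loss = pos_weight * Y * _softplus(-logits) + (1.0 - Y) * _softplus(logits)
    return float(loss.mean())


def _backward(
    params: MLPParams, X: np.ndarray, Y: np.ndarray, pos_weight: np.ndarray
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Gradients of the mean weighted BCE w.r.t. all weights and biases."""
    acts = [X]
    h = X
    n_layers = len(params.weights)
    for i, (w, b) in enumerate(zip(params.weights, params.biases)):
        h = h @ w + b
        if i < n_layers - 1:
            h = np.maximum(h, 0.0)
        acts.append(h)
    logits = acts[-1]
    p = sigmoid(logits)
    n, t = Y.shape
    # d/dz of [w+ * y * softplus(-z) + (1-y) * softplus(z)]
    delta = (-pos_weight * Y * (1.0 - p) + (1.0 - Y) * p) / (n * t)
    grads_w: list[np.ndarray] = [None] * n_layers  # type: ignore[list-item]
    grads_b: list[np.ndarray] = [None] * n_layers  # type: ignore[list-item]
    for i in range(n_layers - 1, -1, -1):
        grads_w[i] = acts[i].T @ delta
        grads_b[i] = delta.sum(axis=0)
        if i > 0:
            delta = (delta @ params.weights[i].T) * (acts[i] > 0.0)
    return grads_w, grads_b


@dataclass
class FitResult:
    params: MLPParams
    n_epochs: int
    best_val_loss: float
    history: list[float] = field(default_factory=list)


def fit_mlp(
    X: np.ndarray,
    Y: np.ndarray,
    layer_sizes: list[int],
    *,
    seed: int,
    pos_weight: np.ndarray | None = None,
    lr: float = 1e-3,
    batch_size: int = 64,
    max_epochs: int = 200,
    patience: int = 15,
    val_fraction: float = 0.1,
) -> FitResult:
    """Train with Adam + early stopping on a seeded validation split.

    The split, the initialization and the per-epoch shuffles all derive from
    ``seed``, so the returned parameters are a pure function of
    (X, Y, layer_sizes, hyperparameters, seed).
    """
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    if pos_weight is None:
        pos_weight = np.ones(Y.shape[1])
    pos_weight = pos_weight[None, :]

    n_val = max(1, int(round(val_fraction * n))) if n >= 10 else 0
    order = rng.permutation(n)
    val_idx, train_idx = order[:n_val], order[n_val:]
    Xtr, Ytr = X[train_idx], Y[train_idx]
    Xva, Yva = X[val_idx], Y[val_idx]

    params = init_params(layer_sizes, rng)
    m = [np.zeros_like(a) for a in params.weights + params.biases]
    v = [np.zeros_like(a) for a in params.weights + params.biases]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0

    best = params.copy()
    best_loss = np.inf
    stale = 0
    history: list[float] = []
    n_epochs_run = 0

    for epoch in range(max_epochs):
        n_epochs_run = epoch + 1
        perm = rng.permutation(len(Xtr))
        for start in range(0, len(Xtr), batch_size):
            idx = perm[start : start + batch_size]
            gw, gb = _backward(params, Xtr[idx], Ytr[idx], pos_weight)
            grads = gw + gb
            tensors = params.weights + params.biases
            step += 1
            for j, (theta, g) in enumerate(zip(tensors, grads)):
                m[j] = beta1 * m[j] + (1 - beta1) * g
                v[j] = beta2 * v[j] + (1 - beta2) * g * g
                mhat = m[j] / (1 - beta1**step)
                vhat = v[j] / (1 - beta2**step)
                theta -= lr * mhat / (np.sqrt(vhat) + eps)
        monitor_X, monitor_Y = (Xva, Yva) if n_val else (Xtr, Ytr)
        val_loss = weighted_bce_loss(forward_logits(params, monitor_X), monitor_Y, pos_weight)
        history.append(val_loss)
        if val_loss < best_loss - 1e-6:
            best_loss = val_loss
            best = params.copy()
            stale = 0
        else:
            stale += 1
            if stale >= patience:
                break
    return FitResult(params=best, n_epochs=n_epochs_run, best_val_loss=best_loss, history=history)
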