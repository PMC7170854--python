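"""Stacked autoencoder for attribute-vector compression.

Greedy layer-wise training of ReLU encoder/decoder pairs under mean
squared reconstruction error, with a seeded Adam optimizer.  Everything is
plain numpy so runs are deterministic for a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)


class SAEError(Exception):
    pass


class DataError(SAEError):
    pass


class ShapeError(SAEError):
    pass


def _relu(z: np.ndarray) -> np.ndarray:
    return np.maximum(z, 0.0)


@dataclass
class _Layer:
    W: np.ndarray   # encoder weight (hidden x in)
    p: np.ndarray   # encoder bias
    W2: np.ndarray  # decoder weight (in x hidden)
    q: np.ndarray   # decoder bias

    def encode(self, X: np.ndarray) -> np.ndarray:
        return _relu(X @ self.W.T + self.p)

    def decode(self, H: np.ndarray) -> np.ndarray:
        return _relu(H @ self.W2.T + self.q)


@dataclass
class SAEModel:
    """Trained stack of encoder/decoder layers plus training provenance."""

    layers: list[_Layer]
    hidden_sizes: tuple[int, ...]
    input_dim: int
    epochs: int
    lr: float
    seed: int
    loss_history: list[list[float]] = field(default_factory=list)

    @property
    def output_dim(self) -> int:
        return self.hidden_sizes[-1]


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _train_layer(
    X: np.ndarray,
    hidden: int,
    epochs: int,
    lr: float,
    batch_size: int,
    rng: np.random.Generator,
) -> tuple[_Layer, list[float]]:
    n, din = X.shape
    # small weights + positive biases start every ReLU active (linear
    # regime); an all-negative pre-activation would never recover gradient
    W = rng.normal(0.0, 0.1, size=(hidden, din))
    p = np.full(hidden, 0.5)
    W2 = rng.normal(0.0, 0.1, size=(din, hidden))
    q = X.mean(axis=0).copy()
    layer = _Layer(W, p, W2, q)
    opt = _Adam([W, p, W2, q], lr)
    losses: list[float] = []
    for _ in range(epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            xb = X[idx]
            zh = xb @ W.T + p
            h = _relu(zh)
            zy = h @ W2.T + q
            y = _relu(zy)
            diff = y - xb
            epoch_loss += float((diff ** 2).sum())
            # backprop of mean squared error through the two ReLU layers
            scale = 2.0 / (xb.shape[0] * din)
            dy = scale * diff * (zy > 0)
            gW2 = dy.T @ h
            gq = dy.sum(axis=0)
            dh = (dy @ W2) * (zh > 0)
            gW = dh.T @ xb
            gp = dh.sum(axis=0)
            opt.step([W, p, W2, q], [gW, gp, gW2, gq])
        losses.append(epoch_loss / (n * din))
    return layer, losses


def sae_train(
    data: np.ndarray,
    hidden_sizes: tuple[int, ...] = (64,),
    epochs: int = 100,
    lr: float = 1e-3,
    seed: int = 0,
    batch_size: int = 32,
) -> SAEModel:
    """Greedy layer-wise training on rows of ``data``.

    Each layer is an independent one-hidden-layer autoencoder fitted to the
    previous layer's encoding; the stacked encoder is the chain of encoder
    halves.
    """
    X = np.asarray(data, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise DataError(f"need a 2-D matrix with >= 2 rows, got shape {X.shape}")
    if not np.isfinite(X).all():
        raise DataError("non-finite values in training data")
    for h in hidden_sizes:
        if h > X.shape[1]:
            logger.warning("hidden size %d exceeds input dimension %d", h, X.shape[1])
    rng = np.random.default_rng(seed)
    layers: list[_Layer] = []
    histories: list[list[float]] = []
    rep = X
    for h in hidden_sizes:
        layer, losses = _train_layer(rep, h, epochs, lr, batch_size, rng)
        layers.append(layer)
        histories.append(losses)
        rep = layer.encode(rep)
    return SAEModel(layers=layers, hidden_sizes=tuple(hidden_sizes),
                    input_dim=X.shape[1], epochs=epochs, lr=lr, seed=seed,
                    loss_history=histories)


def sae_encode(model: SAEModel, x: np.ndarray) -> np.ndarray:
    """Map input vector(s) through the stacked ReLU encoder."""
    X = np.atleast_2d(np.asarray(x, dtype=float))
    if X.shape[1] != model.input_dim:
        raise ShapeError(f"expected input dim {model.input_dim}, got {X.shape[1]}")
    for layer in model.layers:
        X = layer.encode(X)
    return X[0] if np.asarray(x).ndim == 1 else X


def sae_decode(model: SAEModel, h: np.ndarray) -> np.ndarray:
    """Map hidden vector(s) back through the stacked ReLU decoder."""
    H = np.atleast_2d(np.asarray(h, dtype=float))
    if H.shape[1] != model.output_dim:
        raise ShapeError(f"expected hidden dim {model.output_dim}, got {H.shape[1]}")
    for layer in reversed(model.layers):
        H = layer.decode(H)
    return H[0] if np.asarray(h).ndim == 1 else H
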