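"""Global-structure node embeddings via k-step transition-matrix SVD.

For each step order k up to K, the row-stochastic transition matrix is
raised to the k-th power, converted to a shifted, truncated log-probability
matrix, and factorized with a rank-d SVD.  The per-order factors
``U_d sqrt(S_d)`` are concatenated column-wise into one embedding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)


class GraRepError(Exception):
    pass


def transition_matrix(adjacency: np.ndarray) -> np.ndarray:
    """Row-normalized adjacency A = D^-1 S.

    Rows of isolated (degree-zero) nodes are left all-zero and flagged with
    a warning.
    """
    adj = np.asarray(adjacency, dtype=float)
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
        raise GraRepError(f"adjacency must be square, got shape {adj.shape}")
    degrees = adj.sum(axis=1)
    isolated = degrees == 0
    if isolated.any():
        logger.warning("%d isolated node(s) get all-zero transition rows",
                       int(isolated.sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        A = adj / degrees[:, None]
    A[isolated] = 0.0
    return A


def k_step_matrix(A: np.ndarray, k: int) -> np.ndarray:
    """k-th power of the transition matrix (k-step walk probabilities)."""
    if k < 1:
        raise GraRepError(f"step order k must be >= 1, got {k}")
    return np.linalg.matrix_power(A, k)


def log_probability_matrix(Ak: np.ndarray, beta: float) -> np.ndarray:
    """Shifted positive log-probability matrix X^k.

    ``X_ij = log(Ak_ij / Gamma_j) - log(beta)`` with the column normalizer
    ``Gamma_j = sum_p Ak_pj``; entries at zero transition probability, and
    entries that come out negative, are truncated to 0.
    """
    if beta <= 0:
        raise GraRepError(f"beta must be positive, got {beta}")
    Ak = np.asarray(Ak, dtype=float)
    gamma = Ak.sum(axis=0)
    X = np.zeros_like(Ak)
    mask = (Ak > 0) & (gamma > 0)
    with np.errstate(divide="ignore"):
        X[mask] = np.log(Ak[mask] / np.broadcast_to(gamma, Ak.shape)[mask]) - np.log(beta)
    np.clip(X, 0.0, None, out=X)
    return X


def _sign_fix(U: np.ndarray, Vt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # deterministic orientation: largest-|entry| of each left singular vector positive
    for j in range(U.shape[1]):
        idx = int(np.argmax(np.abs(U[:, j])))
        if U[idx, j] < 0:
            U[:, j] = -U[:, j]
            Vt[j, :] = -Vt[j, :]
    return U, Vt


def factorize(X: np.ndarray, d: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rank-d SVD factor of X; returns (W, singular_values, Vt_d).

    ``W = U_d sqrt(S_d)`` is the per-order node representation.  The sign
    convention (largest-magnitude element of each left singular vector made
    positive) makes the output deterministic.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if not 1 <= d <= n:
        raise GraRepError(f"factor rank d={d} out of range [1, {n}]")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    U, Vt = _sign_fix(U[:, :d], Vt[:d, :])
    W = U * np.sqrt(s[:d])
    return W, s[:d], Vt


@dataclass
class EmbeddingMatrix:
    """N x (K*d) behavior vectors, one row per node in network order."""

    W: np.ndarray
    K: int
    d: int
    seed: int | None = None

    @property
    def dim(self) -> int:
        return self.W.shape[1]

    def row(self, position: int) -> np.ndarray:
        return self.W[position]


def grarep_embed(
    adjacency: np.ndarray,
    K: int = 4,
    d: int = 16,
    beta: float | None = None,
    seed: int | None = None,
) -> EmbeddingMatrix:
    """Concatenated k-step representations W = [W^1, ..., W^K].

    ``beta`` defaults to 1/N.  Isolated nodes receive all-zero behavior
    vectors.  ``seed`` is recorded for provenance; the dense SVD itself is
    deterministic.
    """
    if K < 1:
        raise GraRepError(f"K must be >= 1, got {K}")
    A = transition_matrix(adjacency)
    n = A.shape[0]
    if beta is None:
        beta = 1.0 / n
    isolated = np.asarray(adjacency).sum(axis=1) == 0
    blocks = []
    Ak = np.eye(n)
    for _ in range(K):
        Ak = Ak @ A
        X = log_probability_matrix(Ak, beta)
        Wk, _, _ = factorize(X, d)
        blocks.append(Wk)
    W = np.hstack(blocks)
    W[isolated] = 0.0
    return EmbeddingMatrix(W=W, K=K, d=d, seed=seed)
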