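"""Non-negative matrix factorization by Lee-Seung multiplicative updates.

Approximates a non-negative feature matrix ``V (N x D)`` as ``P @ Q``
with ``P (N x rank)`` sample scores and ``Q (rank x D)`` basis rows,
minimising the Frobenius norm ``||V - PQ||_F``.  Multiplicative updates
guarantee a non-increasing objective and preserve non-negativity.

Components are reordered by descending row-norm of Q before return, so
component 1 ("NMF1") is always the dominant basis; NMF columns are
otherwise unordered by nature.  ``nmf_transform`` projects new samples
onto a fixed basis, as needed to score test data with a training basis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

__all__ = ["NMFModel", "nmf_fit", "nmf_transform"]

_EPS = 1e-12


@dataclass
class NMFModel:
    """Fitted factors and convergence metadata.

    Attributes
    ----------
    P : ndarray (N, rank)
        Per-sample scores.
    Q : ndarray (rank, D)
        Basis rows, ordered by descending Euclidean row-norm.
    rank : int
    error_trace : list of float
        Frobenius reconstruction error after each update sweep;
        non-increasing (up to float noise).
    seed : int
    n_iter : int
        Number of update sweeps actually performed.
    """

    P: np.ndarray
    Q: np.ndarray
    rank: int
    error_trace: List[float] = field(default_factory=list)
    seed: int = 0
    n_iter: int = 0

    @property
    def reconstruction_error(self) -> float:
        return self.error_trace[-1] if self.error_trace else np.nan

    def relative_error(self, V: np.ndarray) -> float:
        V = np.asarray(V, float)
        return float(np.linalg.norm(V - self.P @ self.Q) / max(np.linalg.norm(V), _EPS))


def _check_V(V) -> np.ndarray:
    V = np.asarray(V, dtype=float)
    if V.ndim != 2:
        raise ValueError(f"V must be 2-D, got shape {V.shape}")
    if np.any(V < 0):
        raise ValueError("V must be non-negative")
    if not np.all(np.isfinite(V)):
        raise ValueError("V must be finite")
    return V


def _random_init(rng: np.random.Generator, shape, mean: float, rank: int) -> np.ndarray:
    # scale so the initial product has the magnitude of V (standard random init)
    scale = np.sqrt(max(mean, _EPS) / rank)
    return scale * rng.uniform(0.0, 1.0, size=shape) + _EPS


def nmf_fit(
    V,
    rank: int,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> NMFModel:
    """Factor V ~= P Q by multiplicative updates for the Frobenius objective.

    Stops after ``max_iter`` sweeps or when the relative improvement of
    the Frobenius error falls below ``tol``.  Deterministic for a fixed
    seed.

    Raises
    ------
    ValueError
        If ``rank`` exceeds ``min(N, D)`` or V has negative entries.
    """
    V = _check_V(V)
    n, d = V.shape
    if rank < 1 or rank > min(n, d):
        raise ValueError(f"rank must be in [1, min(N, D)] = [1, {min(n, d)}], got {rank}")
    rng = np.random.default_rng(seed)
    mean = float(V.mean())
    P = _random_init(rng, (n, rank), mean, rank)
    Q = _random_init(rng, (rank, d), mean, rank)

    trace: List[float] = []
    prev = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        # Lee-Seung multiplicative updates for ||V - PQ||_F
        Q *= (P.T @ V) / (P.T @ P @ Q + _EPS)
        P *= (V @ Q.T) / (P @ (Q @ Q.T) + _EPS)
        err = float(np.linalg.norm(V - P @ Q))
        trace.append(err)
        if prev < np.inf and prev > 0 and (prev - err) / prev < tol:
            break
        prev = err

    P, Q = _reorder(P, Q)
    return NMFModel(P=P, Q=Q, rank=rank, error_trace=trace, seed=seed, n_iter=it)


def _reorder(P: np.ndarray, Q: np.ndarray):
    """Deterministic component order: descending Euclidean row-norm of Q."""
    norms = np.linalg.norm(Q, axis=1)
    order = np.argsort(-norms, kind="stable")
    return P[:, order], Q[order, :]


def nmf_transform(
    V_new,
    model: NMFModel,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> np.ndarray:
    """Score new samples against a fixed basis Q.

    Finds non-negative ``P_new`` minimising ``||V_new - P_new Q||_F``
    with Q held fixed, by the multiplicative update restricted to P.
    Deterministic given the seed.
    """
    V_new = _check_V(V_new)
    Q = model.Q
    if V_new.shape[1] != Q.shape[1]:
        raise ValueError(
            f"column mismatch: V_new has {V_new.shape[1]} columns, basis expects {Q.shape[1]}"
        )
    n = V_new.shape[0]
    rng = np.random.default_rng(seed)
    P = _random_init(rng, (n, model.rank), float(V_new.mean()), model.rank)
    QQt = Q @ Q.T
    prev = np.inf
    for _ in range(max_iter):
        P *= (V_new @ Q.T) / (P @ QQt + _EPS)
        err = float(np.linalg.norm(V_new - P @ Q))
        if prev < np.inf and prev > 0 and (prev - err) / prev < tol:
            break
        prev = err
    return P
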