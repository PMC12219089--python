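"""Delay embedding and recurrence distance matrices.

A scalar series ``x_1, ..., x_T`` is mapped to k-dimensional state
vectors ``X_i = (x_i, x_{i+tau}, ..., x_{i+(k-1)tau})``; the recurrence
plot is the matrix of pairwise Euclidean distances ``D_ij = d(X_i, X_j)``
viewed as a grayscale image.  Indices are 1-based in documentation
(matching the nonlinear-dynamics convention) and 0-based in code.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "TimeSeries",
    "EmbeddedTrajectory",
    "DistanceMatrix",
    "delay_embed",
    "recurrence_distance_matrix",
]


@dataclass(frozen=True)
class TimeSeries:
    """An ordered univariate real-valued signal with an optional class label."""

    values: np.ndarray
    label: Optional[str] = None
    id: Optional[str] = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1:
            raise ValueError(f"TimeSeries values must be 1-D, got shape {values.shape}")
        if values.size == 0:
            raise ValueError("TimeSeries must contain at least one sample")
        if not np.all(np.isfinite(values)):
            raise ValueError("TimeSeries values must be finite (no NaN/Inf)")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class EmbeddedTrajectory:
    """Rows are delay vectors (x_i, x_{i+tau}, ..., x_{i+(k-1)tau})."""

    points: np.ndarray
    k: int
    tau: int = 1

    @property
    def n_points(self) -> int:
        return int(self.points.shape[0])


@dataclass(frozen=True)
class DistanceMatrix:
    """Square symmetric non-negative matrix of pairwise state distances."""

    entries: np.ndarray
    metric_name: str = "euclidean"

    def __post_init__(self) -> None:
        entries = np.asarray(self.entries, dtype=float)
        if entries.ndim != 2 or entries.shape[0] != entries.shape[1]:
            raise ValueError(f"DistanceMatrix must be square, got shape {entries.shape}")
        object.__setattr__(self, "entries", entries)

    @property
    def n(self) -> int:
        return int(self.entries.shape[0])


def _as_series(series) -> TimeSeries:
    if isinstance(series, TimeSeries):
        return series
    return TimeSeries(np.asarray(series, dtype=float))


def delay_embed(series, k: int, tau: int = 1) -> EmbeddedTrajectory:
    """Delay-embed a univariate series into k-dimensional state vectors.

    Parameters
    ----------
    series : TimeSeries or 1-D array-like
        The signal ``x_1, ..., x_T``.
    k : int
        Embedding dimension (>= 1).
    tau : int, default 1
        Delay in samples between consecutive embedding coordinates.
        The default matches consecutive-sample embedding
        ``X_i = (x_i, x_{i+1}, ..., x_{i+k-1})``.

    Returns
    -------
    EmbeddedTrajectory
        ``T - (k-1)*tau`` rows; row ``i`` (1-based) is
        ``(x_i, x_{i+tau}, ..., x_{i+(k-1)tau})``.
    """
    ts = _as_series(series)
    if k < 1:
        raise ValueError(f"embedding dimension k must be >= 1, got {k}")
    if tau < 1:
        raise ValueError(f"delay tau must be >= 1, got {tau}")
    T = len(ts)
    n_rows = T - (k - 1) * tau
    if n_rows < 1:
        raise ValueError(
            f"series too short for embedding: T={T} requires "
            f"T >= (k-1)*tau + 1 = {(k - 1) * tau + 1} for k={k}, tau={tau}"
        )
    x = ts.values
    # strided view: rows i, columns j -> x[i + j*tau]
    points = np.column_stack([x[j * tau : j * tau + n_rows] for j in range(k)])
    return EmbeddedTrajectory(points=points, k=k, tau=tau)


_METRICS = {"euclidean"}


def recurrence_distance_matrix(
    traj: EmbeddedTrajectory | np.ndarray, metric: str = "euclidean"
) -> DistanceMatrix:
    """Pairwise distance matrix of an embedded trajectory (the recurrence plot).

    Entry ``(i, j)`` is the Euclidean distance between rows ``i`` and ``j``;
    the result is symmetric with a zero diagonal.
    """
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}; available: {sorted(_METRICS)}")
    points = traj.points if isinstance(traj, EmbeddedTrajectory) else np.asarray(traj, float)
    if points.ndim != 2 or points.shape[0] < 1:
        raise ValueError("trajectory must be a 2-D array with at least one row")
    if points.shape[0] == 1:
        entries = np.zeros((1, 1))
    else:
        entries = squareform(pdist(points, metric="euclidean"))
    # pdist/squareform guarantee symmetry and a zero diagonal exactly
    return DistanceMatrix(entries=entries, metric_name=metric)
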