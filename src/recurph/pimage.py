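"""Persistence images: rasterising a diagram into a fixed-length vector.

Each finite (birth, death) point of a diagram is replaced by an
isotropic bivariate Gaussian of bandwidth sigma and the resulting
density is multiplied by a lifetime weight.  Evaluated on a fixed
(birth, death) grid shared across a cohort, this yields comparable
non-negative feature vectors of length nb*nd — the rows of the matrix
fed to NMF.

Weight convention: by default the squared lifetime (d - b)^2 is
evaluated at the *grid* location, following the formula
``PI(b, d) = w(b, d) * sum_i K(b_i - b, d_i - d)`` taken literally,
and clamped to zero below the diagonal.  The standard
persistence-image literature instead weights each diagram point by its
own lifetime; that mode is available as ``weight_mode="point"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, Tuple

import numpy as np

from .cubical import PersistenceDiagram

__all__ = ["PIGridSpec", "grid_from_diagrams", "persistence_image"]

_WEIGHTS = {"squared_lifetime", "one"}
_MODES = {"grid", "point"}


@dataclass(frozen=True)
class PIGridSpec:
    """Evaluation grid and kernel parameters for persistence images.

    Attributes
    ----------
    birth_range, death_range : (float, float)
        Inclusive bounds of the grid on each axis; cell centers are
        placed at the midpoints of a uniform subdivision.
    resolution : (int, int)
        Number of cells (nb, nd) along the birth and death axes.
    sigma : float
        Standard deviation of the isotropic Gaussian kernel, in the
        units of the filtration values (distances).
    weight_name : str
        "squared_lifetime" (default) or "one" (unweighted, for
        normalisation checks).
    weight_mode : str
        "grid" — weight evaluated at the grid location (default);
        "point" — weight evaluated at each diagram point.
    """

    birth_range: Tuple[float, float]
    death_range: Tuple[float, float]
    resolution: Tuple[int, int] = (64, 64)
    sigma: float = 0.1
    weight_name: str = "squared_lifetime"
    weight_mode: str = "grid"

    def __post_init__(self) -> None:
        if self.birth_range[1] <= self.birth_range[0]:
            raise ValueError(f"birth_range max must exceed min: {self.birth_range}")
        if self.death_range[1] <= self.death_range[0]:
            raise ValueError(f"death_range max must exceed min: {self.death_range}")
        nb, nd = self.resolution
        if nb < 1 or nd < 1:
            raise ValueError(f"resolution must be positive: {self.resolution}")
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if self.weight_name not in _WEIGHTS:
            raise ValueError(f"unknown weight {self.weight_name!r}; available: {sorted(_WEIGHTS)}")
        if self.weight_mode not in _MODES:
            raise ValueError(f"unknown weight_mode {self.weight_mode!r}; available: {sorted(_MODES)}")

    def centers(self) -> Tuple[np.ndarray, np.ndarray]:
        """Cell-center coordinates along the birth and death axes."""
        nb, nd = self.resolution
        b0, b1 = self.birth_range
        d0, d1 = self.death_range
        bc = b0 + (np.arange(nb) + 0.5) * (b1 - b0) / nb
        dc = d0 + (np.arange(nd) + 0.5) * (d1 - d0) / nd
        return bc, dc

    @property
    def cell_area(self) -> float:
        nb, nd = self.resolution
        return ((self.birth_range[1] - self.birth_range[0]) / nb) * (
            (self.death_range[1] - self.death_range[0]) / nd
        )

    @property
    def n_cells(self) -> int:
        return self.resolution[0] * self.resolution[1]


def grid_from_diagrams(
    diagrams: Iterable[PersistenceDiagram],
    resolution: Tuple[int, int] = (64, 64),
    sigma_rule=None,
    weight_name: str = "squared_lifetime",
    weight_mode: str = "grid",
) -> PIGridSpec:
    """Build one shared grid covering every diagram of a cohort.

    Bounds are ``[0, max death]`` on both axes, padded by 3*sigma on
    each side so the Gaussian mass of boundary points stays on the
    grid.  The default bandwidth rule is sigma = 0.05 * (max death -
    min birth).  Deterministic given the inputs.
    """
    max_death = -np.inf
    min_birth = np.inf
    for dg in diagrams:
        arr = dg.births_deaths()
        if arr.shape[0] == 0:
            continue
        max_death = max(max_death, float(arr[:, 1].max()))
        min_birth = min(min_birth, float(arr[:, 0].min()))
    if not np.isfinite(max_death):
        raise ValueError("all diagrams are empty; cannot infer grid bounds")
    if sigma_rule is None:
        sigma = 0.05 * (max_death - min_birth)
    else:
        sigma = float(sigma_rule(min_birth, max_death))
    if sigma <= 0:
        raise ValueError(f"degenerate diagrams: derived sigma {sigma} is not positive")
    lo, hi = 0.0 - 3.0 * sigma, max_death + 3.0 * sigma
    return PIGridSpec(
        birth_range=(lo, hi),
        death_range=(lo, hi),
        resolution=resolution,
        sigma=sigma,
        weight_name=weight_name,
        weight_mode=weight_mode,
    )


def persistence_image(diagram: PersistenceDiagram, grid: PIGridSpec) -> np.ndarray:
    """Rasterise a diagram into a non-negative vector of length nb*nd.

    For each grid-cell center (b, d):

        PI(b, d) = w(b, d) * sum_i g(b_i - b, d_i - d)

    with g the bivariate isotropic Gaussian density
    ``exp(-(x^2 + y^2) / (2 sigma^2)) / (2 pi sigma^2)`` and, in the
    default grid-weight mode, ``w(b, d) = max(d - b, 0)^2``.  The
    Gaussian is separable, so the sum over diagram points is computed
    as a product of one-dimensional kernel matrices.

    An empty diagram yields the zero vector.  Row-major over the grid:
    birth index varies slowest.
    """
    nb, nd = grid.resolution
    pts = diagram.births_deaths()
    if pts.shape[0] == 0:
        return np.zeros(nb * nd)
    bc, dc = grid.centers()
    sig2 = grid.sigma ** 2
    # (n_points, nb) and (n_points, nd) 1-D kernel factors
    gb = np.exp(-((pts[:, [0]] - bc[None, :]) ** 2) / (2.0 * sig2))
    gd = np.exp(-((pts[:, [1]] - dc[None, :]) ** 2) / (2.0 * sig2))
    norm = 1.0 / (2.0 * np.pi * sig2)
    if grid.weight_mode == "point":
        wpt = _point_weight(pts, grid.weight_name)
        density = (gb * wpt[:, None]).T @ gd
        img = norm * density
    else:
        density = gb.T @ gd  # (nb, nd) sum of unit Gaussians
        img = norm * density * _grid_weight(bc, dc, grid.weight_name)
    return img.ravel()


def _grid_weight(bc: np.ndarray, dc: np.ndarray, name: str) -> np.ndarray:
    if name == "one":
        return np.ones((bc.size, dc.size))
    lifetime = np.clip(dc[None, :] - bc[:, None], 0.0, None)
    return lifetime ** 2


def _point_weight(pts: np.ndarray, name: str) -> np.ndarray:
    if name == "one":
        return np.ones(pts.shape[0])
    return np.clip(pts[:, 1] - pts[:, 0], 0.0, None) ** 2
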