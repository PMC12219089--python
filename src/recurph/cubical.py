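"""0-dimensional sublevel persistent homology of a grayscale matrix.

The filtration is by pixel value: the sublevel set ``S(r)`` contains
every pixel with value <= r.  Adjacency is the V-construction: pixels
are connected only when they share an edge (4-neighbourhood); corner
contact does not connect.  As r grows, connected components of S(r)
appear at local minima ("birth") and are absorbed into older components
at saddles ("death", elder rule).  The output is the multiset of finite
(birth, death) pairs plus one essential birth per connected component
of the full image.

Algorithm: pixels are activated in ascending (value, row-major index)
order and merged with already-active 4-neighbours through a union-find
structure.  At a merge occurring at pixel value v, the component with
the larger birth dies with death v; a tie on birth is broken in favour
of the component whose root pixel was activated earlier.  Deterministic
for a fixed matrix.

``sublevel_betti0`` is an independent flood-fill component counter kept
in the shipped code as the testing oracle for the union-find path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage

__all__ = [
    "PersistencePair",
    "PersistenceDiagram",
    "sublevel_betti0",
    "persistence_h0",
    "write_diagram",
    "read_diagram",
]

# V-construction adjacency: edge-sharing neighbours only
_V_STRUCTURE = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass(frozen=True)
class PersistencePair:
    """A finite component feature: born at a local minimum, dead at a saddle."""

    birth: float
    death: float
    birth_location: Optional[Tuple[int, int]] = None

    @property
    def persistence(self) -> float:
        return self.death - self.birth


@dataclass
class PersistenceDiagram:
    """Multiset of finite (birth, death) pairs plus essential births.

    ``finite_pairs`` hold components absorbed at a finite threshold;
    ``essential_births`` hold the birth values of components that never
    merge (one per connected component of the full image).
    """

    finite_pairs: List[PersistencePair] = field(default_factory=list)
    essential_births: List[float] = field(default_factory=list)

    def births_deaths(self) -> np.ndarray:
        """Finite pairs as an (n, 2) array, sorted for stable comparison."""
        if not self.finite_pairs:
            return np.empty((0, 2))
        arr = np.array([(p.birth, p.death) for p in self.finite_pairs])
        order = np.lexsort((arr[:, 1], arr[:, 0]))
        return arr[order]

    def betti0_at(self, r: float) -> int:
        """Number of components alive at threshold r implied by the diagram."""
        alive = sum(1 for p in self.finite_pairs if p.birth <= r < p.death)
        alive += sum(1 for b in self.essential_births if b <= r)
        return alive

    def __len__(self) -> int:
        return len(self.finite_pairs)


def _validate_image(image) -> np.ndarray:
    arr = np.asarray(image, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError(f"image must be a non-empty 2-D matrix, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("image values must be finite")
    return arr


def sublevel_betti0(image, r: float) -> int:
    """Count connected components of ``{pixels <= r}`` under edge adjacency.

    Brute-force flood fill (via labelled connected components); this is
    the independent oracle against which the persistence algorithm is
    verified, kept in the shipped code for testing.
    """
    arr = _validate_image(image)
    mask = arr <= r
    if not mask.any():
        return 0
    _, n = ndimage.label(mask, structure=_V_STRUCTURE)
    return int(n)


def persistence_h0(
    image, keep_zero_persistence: bool = False
) -> PersistenceDiagram:
    """0-dimensional sublevel persistence of a 2-D matrix (V-construction).

    Parameters
    ----------
    image : 2-D array-like
        Grayscale matrix; any finite real values.
    keep_zero_persistence : bool, default False
        Zero-lifetime pairs (death == birth, produced by merges among
        equal-valued pixels) are discarded by default: they carry zero
        weight in the persistence image and bloat the diagram.

    Returns
    -------
    PersistenceDiagram
        Finite (birth, death) pairs with the birth pixel of the dying
        component recorded, plus one essential birth per connected
        component of the full image.
    """
    arr = _validate_image(image)
    h, w = arr.shape
    n = h * w
    flat = arr.ravel()

    # activation order: ascending value, ties by row-major index
    order = np.lexsort((np.arange(n), flat))

    parent = np.full(n, -1, dtype=np.int64)  # -1 = not yet activated
    birth_val = np.empty(n, dtype=float)     # valid at roots
    birth_pix = np.empty(n, dtype=np.int64)  # root pixel of the component minimum
    activation = np.empty(n, dtype=np.int64)  # activation rank, for tie-breaks

    def find(i: int) -> int:
        root = i
        while parent[root] != root:
            root = parent[root]
        while parent[i] != root:  # path compression
            parent[i], i = root, parent[i]
        return root

    pairs: List[PersistencePair] = []

    for rank, idx in enumerate(order):
        v = flat[idx]
        parent[idx] = idx
        birth_val[idx] = v
        birth_pix[idx] = idx
        activation[idx] = rank
        r, c = divmod(int(idx), w)
        for nb in _neighbors(r, c, h, w):
            if parent[nb] < 0:
                continue  # not active yet
            ra, rb = find(int(idx)), find(nb)
            if ra == rb:
                continue
            # elder rule: smaller birth survives; tie -> earlier activation
            if (birth_val[ra], activation[ra]) <= (birth_val[rb], activation[rb]):
                elder, younger = ra, rb
            else:
                elder, younger = rb, ra
            death = v
            b = birth_val[younger]
            if keep_zero_persistence or death > b:
                loc = divmod(int(birth_pix[younger]), w)
                pairs.append(PersistencePair(float(b), float(death), loc))
            parent[younger] = elder

    # roots after all unions are exactly the surviving components
    roots = {find(i) for i in range(n)}
    essential = sorted(float(birth_val[r]) for r in roots)
    return PersistenceDiagram(finite_pairs=pairs, essential_births=essential)


def _neighbors(r: int, c: int, h: int, w: int):
    if r > 0:
        yield (r - 1) * w + c
    if r < h - 1:
        yield (r + 1) * w + c
    if c > 0:
        yield r * w + c - 1
    if c < w - 1:
        yield r * w + c + 1


# ---------------------------------------------------------------------------
# diagram I/O: delimited text with columns dim,birth,death ("inf" = essential)

def write_diagram(diagram: PersistenceDiagram, path) -> None:
    """Write a diagram as CSV with columns dim,birth,death; essential deaths
    are serialised as the literal token ``inf``."""
    with open(path, "w") as fh:
        fh.write("dim,birth,death\n")
        for p in diagram.finite_pairs:
            fh.write(f"0,{p.birth!r},{p.death!r}\n")
        for b in diagram.essential_births:
            fh.write(f"0,{b!r},inf\n")


def read_diagram(path) -> PersistenceDiagram:
    """Read a diagram written by :func:`write_diagram`; exact round-trip."""
    pairs: List[PersistencePair] = []
    essential: List[float] = []
    with open(path) as fh:
        header = fh.readline()
        if header.strip() != "dim,birth,death":
            raise ValueError(f"{path}: line 1: expected header 'dim,birth,death'")
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            fields = line.split(",")
            if len(fields) != 3:
                raise ValueError(f"{path}: line {lineno}: expected 3 fields, got {len(fields)}")
            try:
                dim = int(fields[0])
                birth = float(fields[1])
                death = float("inf") if fields[2] == "inf" else float(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
            if dim != 0:
                raise ValueError(f"{path}: line {lineno}: only dimension 0 supported")
            if np.isinf(death):
                essential.append(birth)
            else:
                pairs.append(PersistencePair(birth, death))
    return PersistenceDiagram(finite_pairs=pairs, essential_births=sorted(essential))
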