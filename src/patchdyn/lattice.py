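"""Lattice geometries for percolation-map landscapes.

Two regular lattices are supported, both wrapped onto a torus:

``hex6``
    The six-neighbour triangular adjacency in axial coordinates on an
    L x L rhombic torus: neighbours of (i, j) are (i±1, j), (i, j±1),
    (i+1, j−1) and (i−1, j+1), all modulo L.  This is the standard
    lattice with exact site-percolation threshold p_c = 1/2.

``square4``
    The square lattice with von Neumann (4-orthogonal-neighbour)
    adjacency; its site-percolation threshold is p_c ≈ 0.592746.

Sites are indexed 0-based row-major; coordinates are (row, col) and all
wraps use modular arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

HEX6 = "hex6"
SQUARE4 = "square4"
KINDS = (HEX6, SQUARE4)

#: Reference site-percolation thresholds (habitat fraction p_c).
REFERENCE_PC = {HEX6: 0.5, SQUARE4: 0.592746}

# Neighbour directions.  For hex6 the order is a cyclic ring: consecutive
# directions point at mutually adjacent sites, which is what the
# group-lookup tables below rely on.
_DIRS = {
    HEX6: ((0, 1), (1, 0), (1, -1), (0, -1), (-1, 0), (-1, 1)),
    SQUARE4: ((-1, 0), (0, 1), (1, 0), (0, -1)),
}

# "Ring" of sites surrounding a site, in cyclic order such that consecutive
# ring sites are themselves lattice neighbours.  For hex6 the ring is the
# neighbourhood itself; for square4 it is the 8-site Moore ring, in which
# the von Neumann neighbours occupy every second position and the diagonal
# sites act only as potential connectors between them.
_RING = {
    HEX6: _DIRS[HEX6],
    SQUARE4: (
        (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1),
    ),
}

# Position of each neighbour direction inside the ring.
_CROSS = {HEX6: (0, 1, 2, 3, 4, 5), SQUARE4: (0, 2, 4, 6)}

# scipy.ndimage.label structuring elements (open, non-periodic grid).
_STRUCTURE = {
    HEX6: np.array([[0, 1, 1], [1, 1, 1], [1, 1, 0]], dtype=bool),
    SQUARE4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
}


def _validate_kind(kind: str) -> str:
    if kind not in KINDS:
        raise ValueError(f"unknown lattice kind {kind!r}; expected one of {KINDS}")
    return kind


@dataclass(frozen=True)
class Lattice:
    """Geometry descriptor: kind, side length and torus topology."""

    kind: str
    side: int

    def __post_init__(self) -> None:
        _validate_kind(self.kind)
        if not isinstance(self.side, (int, np.integer)) or self.side < 3:
            raise ValueError("side length must be an integer >= 3")
        object.__setattr__(self, "side", int(self.side))

    @property
    def n_sites(self) -> int:
        return self.side * self.side

    @property
    def coordination(self) -> int:
        """Number of neighbours per site (z)."""
        return len(_DIRS[self.kind])

    @property
    def p_c(self) -> float:
        """Reference site-percolation threshold for this geometry."""
        return REFERENCE_PC[self.kind]

    @property
    def q_c(self) -> float:
        return 1.0 - self.p_c

    # -- indexing -----------------------------------------------------
    def site_index(self, row: int, col: int) -> int:
        return (row % self.side) * self.side + (col % self.side)

    def coords(self, site: int) -> tuple[int, int]:
        self._check_site(site)
        return divmod(int(site), self.side)

    def _check_site(self, site: int) -> None:
        if not 0 <= int(site) < self.n_sites:
            raise ValueError(
                f"site index {site} out of range for {self.n_sites} sites"
            )

    # -- adjacency ----------------------------------------------------
    @property
    def neighbor_array(self) -> np.ndarray:
        """(n_sites, z) array of torus-wrapped neighbour indices."""
        return _neighbor_array(self.kind, self.side)

    def neighbors(self, site: int) -> list[int]:
        """The z distinct neighbours of ``site``, torus-wrapped."""
        self._check_site(site)
        return [int(x) for x in self.neighbor_array[int(site)]]

    @property
    def ring_array(self) -> np.ndarray:
        """(n_sites, R) array of surrounding-ring indices (see module doc)."""
        return _ring_array(self.kind, self.side)

    @property
    def ring_tables(self) -> tuple[np.ndarray, np.ndarray]:
        """Occupancy-mask lookup tables for grouping habitat neighbours.

        Returns ``(n_groups, group_of)`` where for a ring-occupancy bitmask
        ``m``, ``n_groups[m]`` is the number of ring-connected groups that
        contain at least one true neighbour, and ``group_of[m, d]`` is the
        compact group id of neighbour direction ``d`` (−1 if that
        neighbour is not occupied).
        """
        return _ring_tables(self.kind)

    @property
    def cross_positions(self) -> np.ndarray:
        return np.array(_CROSS[self.kind], dtype=np.int64)

    @property
    def label_structure(self) -> np.ndarray:
        return _STRUCTURE[self.kind]

    def wrap_edges(self) -> list[tuple[np.ndarray, np.ndarray, tuple[int, int]]]:
        """Edges of the torus not present in the open (cut) grid.

        Returns one ``(u, v, delta)`` batch per crossing direction, where
        ``u`` and ``v`` are flat site indices with ``v = u + delta``
        modulo the torus.
        """
        return _wrap_edges(self.kind, self.side)


@lru_cache(maxsize=None)
def _offsets_to_indices(kind: str, side: int, offsets: tuple) -> np.ndarray:
    n = side * side
    rows, cols = np.divmod(np.arange(n), side)
    out = np.empty((n, len(offsets)), dtype=np.int32)
    for k, (di, dj) in enumerate(offsets):
        out[:, k] = ((rows + di) % side) * side + (cols + dj) % side
    return out


@lru_cache(maxsize=None)
def _neighbor_array(kind: str, side: int) -> np.ndarray:
    return _offsets_to_indices(kind, side, _DIRS[kind])


@lru_cache(maxsize=None)
def _ring_array(kind: str, side: int) -> np.ndarray:
    return _offsets_to_indices(kind, side, _RING[kind])


@lru_cache(maxsize=None)
def _ring_tables(kind: str) -> tuple[np.ndarray, np.ndarray]:
    ring = _RING[kind]
    cross = _CROSS[kind]
    n_ring = len(ring)
    z = len(_DIRS[kind])
    n_groups = np.zeros(1 << n_ring, dtype=np.uint8)
    group_of = np.full((1 << n_ring, z), -1, dtype=np.int8)
    for mask in range(1 << n_ring):
        # Connected components of the occupied ring positions in the cyclic
        # ring graph C_R (consecutive ring sites are lattice neighbours).
        comp = [-1] * n_ring
        cid = 0
        for r in range(n_ring):
            if mask >> r & 1 and comp[r] < 0:
                stack = [r]
                comp[r] = cid
                while stack:
                    x = stack.pop()
                    for y in ((x + 1) % n_ring, (x - 1) % n_ring):
                        if mask >> y & 1 and comp[y] < 0:
                            comp[y] = cid
                            stack.append(y)
                cid += 1
        compact: dict[int, int] = {}
        for d, rpos in enumerate(cross):
            if mask >> rpos & 1:
                c = comp[rpos]
                if c not in compact:
                    compact[c] = len(compact)
                group_of[mask, d] = compact[c]
        n_groups[mask] = len(compact)
    return n_groups, group_of


@lru_cache(maxsize=None)
def _wrap_edges(kind: str, side: int):
    # One undirected batch per direction in the positive half of the
    # neighbourhood; the open grid already contains all non-wrapping edges.
    half = {
        HEX6: ((0, 1), (1, 0), (1, -1)),
        SQUARE4: ((0, 1), (1, 0)),
    }[kind]
    n = side * side
    rows, cols = np.divmod(np.arange(n), side)
    batches = []
    for di, dj in half:
        wraps = ((rows + di < 0) | (rows + di >= side)
                 | (cols + dj < 0) | (cols + dj >= side))
        u = np.flatnonzero(wraps).astype(np.int64)
        v = (((rows[u] + di) % side) * side + (cols[u] + dj) % side).astype(np.int64)
        batches.append((u, v, (di, dj)))
    return batches
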