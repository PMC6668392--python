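"""Plain-text raster I/O for binary landscapes.

The raster format is L lines of L characters, ``'1'`` for habitat and
``'0'`` for non-habitat; the reader and writer round-trip exactly.  The
lattice kind is not part of the file and must be supplied when a
:class:`~patchdyn.landscape.Landscape` is built from a raster.

A minimal ASCII PGM (P2) snapshot export is provided for quick looks:
habitat sites render grey, non-habitat sites white.
"""

from __future__ import annotations

import os

import numpy as np

from .landscape import Landscape


def read_raster(path: os.PathLike | str) -> np.ndarray:
    """Read a 0/1 text raster into an (L, L) uint8 array."""
    with open(path, "r", encoding="ascii") as fh:
        lines = [line.rstrip("\n") for line in fh if line.strip() != ""]
    if not lines:
        raise ValueError(f"{path}: empty raster")
    L = len(lines)
    rows = []
    for i, line in enumerate(lines):
        if len(line) != L:
            raise ValueError(
                f"{path}: line {i + 1} has {len(line)} characters, "
                f"expected {L} (raster must be square)"
            )
        bad = set(line) - {"0", "1"}
        if bad:
            raise ValueError(f"{path}: invalid characters {sorted(bad)} on line {i + 1}")
        rows.append([1 if c == "1" else 0 for c in line])
    return np.array(rows, dtype=np.uint8)


def write_raster(grid: np.ndarray | Landscape, path: os.PathLike | str) -> None:
    """Write an (L, L) binary grid (or a Landscape) as a 0/1 text raster."""
    if isinstance(grid, Landscape):
        grid = grid.grid
    grid = np.asarray(grid, dtype=np.uint8)
    if grid.ndim != 2:
        raise ValueError("grid must be 2-D")
    with open(path, "w", encoding="ascii") as fh:
        for row in grid:
            fh.write("".join("1" if v else "0" for v in row))
            fh.write("\n")


def landscape_from_raster(kind: str, path: os.PathLike | str) -> Landscape:
    return Landscape.from_grid(kind, read_raster(path))


def write_pgm(grid: np.ndarray | Landscape, path: os.PathLike | str,
              habitat_grey: int = 160) -> None:
    """Export a snapshot as an ASCII PGM (P2) image.

    Habitat sites are rendered grey (``habitat_grey``), non-habitat sites
    white, mirroring the usual percolation-map illustration convention.
    """
    if isinstance(grid, Landscape):
        grid = grid.grid
    grid = np.asarray(grid, dtype=np.uint8)
    img = np.where(grid == 1, habitat_grey, 255)
    with open(path, "w", encoding="ascii") as fh:
        fh.write(f"P2\n{grid.shape[1]} {grid.shape[0]}\n255\n")
        for row in img:
            fh.write(" ".join(str(int(v)) for v in row))
            fh.write("\n")
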