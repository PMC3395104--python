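"""Rectangular maps of hexagonal cells.

The map is a rectangle of hexagons in "odd-r" offset layout: rows are
horizontal, odd-numbered rows are shifted half a cell to the right.  Cells
are addressed either as ``(row, col)`` offset coordinates or as flat
0-based row-major indices.  Distances between cells are hexagonal lattice
(ring-count) distances, computed exactly via cube coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["GridSpec", "map_distance", "neighbourhood", "default_map_size"]


@dataclass(frozen=True)
class GridSpec:
    """A rectangular grid of hexagonal cells.

    Parameters
    ----------
    n_rows, n_cols
        Grid dimensions; both must be at least 1.
    layout
        Offset convention tag.  Only ``"hex-odd-r"`` (odd rows shifted
        half a cell right) is supported.
    """

    n_rows: int
    n_cols: int
    layout: str = "hex-odd-r"

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid dimensions must be positive")
        if self.layout != "hex-odd-r":
            raise ValueError(f"unsupported layout: {self.layout!r}")

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def index(self, row: int, col: int) -> int:
        """Flat row-major index of offset coordinates (row, col)."""
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise IndexError(f"cell ({row}, {col}) outside {self.n_rows}x{self.n_cols} grid")
        return row * self.n_cols + col

    def coords(self, cell: int) -> tuple[int, int]:
        """Offset coordinates (row, col) of a flat cell index."""
        self._check(cell)
        return divmod(cell, self.n_cols)

    def _check(self, cell: int) -> None:
        if not (0 <= int(cell) < self.n_cells):
            raise IndexError(f"cell index {cell} outside [0, {self.n_cells})")

    # -- cube coordinates -------------------------------------------------

    def _cube(self, cell: int) -> tuple[int, int, int]:
        row, col = self.coords(cell)
        # odd-r offset -> cube: odd rows are shoved right
        x = col - (row - (row & 1)) // 2
        z = row
        return x, -x - z, z

    def cube_coords(self) -> np.ndarray:
        """(n_cells, 3) integer cube coordinates of every cell, row-major."""
        rows, cols = np.divmod(np.arange(self.n_cells), self.n_cols)
        x = cols - (rows - (rows & 1)) // 2
        z = rows
        return np.stack([x, -x - z, z], axis=1)

    def distance_matrix(self) -> np.ndarray:
        """All-pairs hexagonal lattice distances, shape (n_cells, n_cells)."""
        cube = self.cube_coords()
        return np.abs(cube[:, None, :] - cube[None, :, :]).max(axis=2)

    def neighbour_lists(self) -> list[list[int]]:
        """Immediate (ring-1) neighbours of every cell."""
        d = self.distance_matrix()
        return [list(np.flatnonzero(d[c] == 1)) for c in range(self.n_cells)]

    def to_dict(self) -> dict:
        return {"n_rows": self.n_rows, "n_cols": self.n_cols, "layout": self.layout}

    @classmethod
    def from_dict(cls, d: dict) -> "GridSpec":
        return cls(int(d["n_rows"]), int(d["n_cols"]), d.get("layout", "hex-odd-r"))


def map_distance(grid: GridSpec, a: int, b: int) -> int:
    """Hexagonal lattice distance (number of cell hops) between two cells.

    Offset coordinates are converted to cube coordinates; the distance is
    the maximum absolute difference over the three cube axes, which equals
    the breadth-first hop count over the hexagonal neighbour graph.
    """
    ax, ay, az = grid._cube(a)
    bx, by, bz = grid._cube(b)
    return max(abs(ax - bx), abs(ay - by), abs(az - bz))


def neighbourhood(grid: GridSpec, centre: int, radius: float) -> set[int]:
    """All cells within ``floor(radius)`` lattice hops of ``centre``.

    The centre itself is always included (radius 0 gives ``{centre}``).
    """
    if radius < 0:
        raise ValueError("radius must be non-negative")
    grid._check(centre)
    r = math.floor(radius)
    cube = grid.cube_coords()
    d = np.abs(cube - cube[centre]).max(axis=1)
    return set(np.flatnonzero(d <= r).tolist())


def default_map_size(n_samples: int, aspect: float = 1.5) -> GridSpec:
    """Pick a map size of roughly three cells per training sample.

    Searches (rows, cols) pairs for the cell count closest to
    ``3 * n_samples``, preferring the pair whose rows/cols ratio is closest
    to ``aspect``.  Never returns a grid smaller than 2x2; the 3x rule is a
    heuristic and map size should be overridden for crowded or sparse maps.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be positive")
    if aspect <= 0:
        raise ValueError("aspect must be positive")
    target = max(4, 3 * n_samples)
    hi = int(math.ceil(math.sqrt(target * max(aspect, 1.0 / aspect)))) + 2
    best = None
    for rows in range(2, hi + 1):
        for cols in range(2, hi + 1):
            key = (abs(rows * cols - target), abs(rows / cols - aspect), rows, cols)
            if best is None or key < best:
                best = key
    _, _, rows, cols = best
    if aspect >= 1 and rows < cols:
        rows, cols = cols, rows
    return GridSpec(rows, cols)
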