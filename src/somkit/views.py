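"""Map visualisation surfaces: BMUs, hit histograms, class maps, U-matrix
and scaled component planes.

Every view is a flat length-``n_cells`` array in row-major cell order; use
``values.reshape(grid.n_rows, grid.n_cols)`` to lay it on the map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .core import Codebook, Dataset
from .grid import GridSpec

__all__ = [
    "assign_bmus",
    "hit_histogram",
    "class_map",
    "ClassMap",
    "u_matrix",
    "component_plane",
    "plot_map",
]


def assign_bmus(codebook: Codebook, data: Dataset | np.ndarray) -> np.ndarray:
    """Per-sample BMU cell indices (ties to the lowest index)."""
    X = data.X if isinstance(data, Dataset) else np.asarray(data, dtype=float)
    if X.ndim != 2 or X.shape[1] != codebook.n_vars:
        raise ValueError(
            f"data has shape {X.shape}, expected (*, {codebook.n_vars})"
        )
    if not np.isfinite(X).all():
        raise ValueError("data contains non-finite values")
    d = cdist(X, codebook.W, metric="sqeuclidean")
    return d.argmin(axis=1)


def hit_histogram(bmus: np.ndarray, grid: GridSpec) -> np.ndarray:
    """Per-cell count of samples whose BMU is that cell; sums to n_samples."""
    bmus = np.asarray(bmus, dtype=int)
    if bmus.size and (bmus.min() < 0 or bmus.max() >= grid.n_cells):
        raise IndexError("BMU index outside grid")
    return np.bincount(bmus, minlength=grid.n_cells)


@dataclass
class ClassMap:
    """Per-cell class fractions: row c gives cell c's membership mixture.

    Each cell is attributed to the class(es) of its nearest BMU cell(s) in
    map distance.  When several BMU cells tie for nearest, the fractions
    are proportional to how many samples of each class those tying cells
    host, so a cell equally close to two single-sample class-A BMUs and
    one class-B BMU is 2/3 A and 1/3 B.
    """

    F: np.ndarray  # (n_cells, n_classes), rows sum to 1
    class_ids: list[str]
    grid: GridSpec

    def dominant(self) -> np.ndarray:
        """Index of the majority class per cell (ties to lowest class index)."""
        return self.F.argmax(axis=1)


def class_map(bmus: np.ndarray, labels, grid: GridSpec, class_ids: list[str] | None = None) -> ClassMap:
    """Shade every map cell by the class mixture of its nearest BMU(s)."""
    bmus = np.asarray(bmus, dtype=int)
    labels = np.asarray(labels)
    if bmus.size == 0:
        raise ValueError("class_map needs at least one BMU")
    if labels.shape[0] != bmus.shape[0]:
        raise ValueError("labels and BMUs are not aligned")
    if class_ids is None:
        class_ids = sorted(set(str(l) for l in labels))
    lab_idx = np.array([class_ids.index(str(l)) for l in labels])
    D = grid.distance_matrix()
    d_to_bmus = D[:, bmus]  # (n_cells, n_samples) distance to each sample's BMU cell
    mins = d_to_bmus.min(axis=1, keepdims=True)
    F = np.zeros((grid.n_cells, len(class_ids)))
    for c in range(grid.n_cells):
        mask = d_to_bmus[c] == mins[c]
        counts = np.bincount(lab_idx[mask], minlength=len(class_ids))
        F[c] = counts / counts.sum()
    return ClassMap(F, list(class_ids), grid)


def u_matrix(codebook: Codebook, mode: str = "mean") -> np.ndarray:
    """Unified distance matrix: per-cell dissimilarity to ring-1 neighbours.

    Low values mean the neighbourhood is homogeneous; ridges of high
    values mark borders between clusters.  ``mode="mean"`` (default)
    averages the Euclidean distances to the immediate neighbours so that
    edge cells, which have fewer neighbours, remain comparable to interior
    ones; ``mode="sum"`` gives the plain summed dissimilarity.
    """
    if mode not in ("mean", "sum"):
        raise ValueError("mode must be 'mean' or 'sum'")
    grid = codebook.grid
    neighbours = grid.neighbour_lists()
    u = np.zeros(grid.n_cells)
    for c, nbrs in enumerate(neighbours):
        dists = np.linalg.norm(codebook.W[nbrs] - codebook.W[c], axis=1)
        u[c] = dists.mean() if mode == "mean" else dists.sum()
    return u


def component_plane(codebook: Codebook, var_index: int) -> np.ndarray:
    """Variable slice of the codebook, min-max scaled to [0, 1].

    The most positive weight maps to 1 and the least positive to 0.  A
    constant column (no contrast to display) maps to all zeros.
    """
    col = codebook.W[:, var_index]
    lo, hi = col.min(), col.max()
    if hi == lo:
        return np.zeros_like(col)
    return (col - lo) / (hi - lo)


def plot_map(values: np.ndarray, grid: GridSpec, ax=None, cmap: str = "viridis", title: str | None = None):
    """Render a per-cell surface as a hexagonal heat map (matplotlib).

    Returns the matplotlib Axes.  Import of matplotlib is deferred so the
    numerical API works headless without it being loaded.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.collections import PatchCollection
    from matplotlib.patches import RegularPolygon

    values = np.asarray(values, dtype=float)
    if values.shape != (grid.n_cells,):
        raise ValueError("values must have one entry per cell")
    if ax is None:
        _, ax = plt.subplots(figsize=(max(4, grid.n_cols / 3), max(3, grid.n_rows / 3)))
    patches = []
    for cell in range(grid.n_cells):
        row, col = grid.coords(cell)
        x = col + 0.5 * (row % 2)
        y = row * np.sqrt(3) / 2
        patches.append(RegularPolygon((x, y), numVertices=6, radius=1 / np.sqrt(3)))
    pc = PatchCollection(patches, cmap=cmap)
    pc.set_array(values)
    ax.add_collection(pc)
    ax.autoscale_view()
    ax.set_aspect("equal")
    ax.invert_yaxis()
    ax.set_xticks([])
    ax.set_yticks([])
    if title:
        ax.set_title(title)
    ax.figure.colorbar(pc, ax=ax, shrink=0.8)
    return ax
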