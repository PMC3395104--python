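"""SOMDI (SOM discrimination index) variable ranking.

A variable's scaled component plane is compared with a class component
plane (1 where the cell's nearest BMUs all belong to the class, 0 where
none do, intermediate on ties).  The elementwise product summed over the
map is the index of that variable for that class; subtracting the index
of the merged complement classes gives a signed discrimination score —
positive for a marker of the class, negative for a marker of the rest.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .core import Codebook
from .grid import GridSpec
from .views import class_map, component_plane

__all__ = [
    "class_component_plane",
    "somdi_index",
    "discrimination_score",
    "rank_variables",
    "somdi_table",
]


def class_component_plane(bmus, labels, grid: GridSpec, class_id: str) -> np.ndarray:
    """Per-cell membership of one class, using the class-map tie rule.

    Equals the corresponding column of :func:`somkit.views.class_map`:
    a cell equally close to two single-sample class-A BMUs and one
    class-B BMU scores 2/3 on class A.
    """
    labels = np.asarray(labels)
    class_id = str(class_id)
    present = set(str(l) for l in labels)
    if class_id not in present:
        raise ValueError(f"class {class_id!r} not present among labels")
    cm = class_map(bmus, labels, grid)
    return cm.F[:, cm.class_ids.index(class_id)]


def somdi_index(plane: np.ndarray, qplane: np.ndarray) -> float:
    """Index of how strongly a variable represents a class: the scaled
    component plane multiplied elementwise with the class component plane
    and summed over all cells."""
    plane = np.asarray(plane, dtype=float)
    qplane = np.asarray(qplane, dtype=float)
    if plane.shape != qplane.shape:
        raise ValueError("component plane and class plane are on different grids")
    return float(plane @ qplane)


def _merged_complement_plane(bmus, labels, grid: GridSpec, class_id: str) -> np.ndarray:
    """Class plane of 'everything except class_id', all other classes
    merged into one; with a full partition this is 1 - q_class cellwise."""
    labels = np.asarray([str(l) for l in labels], dtype=object)
    merged = np.where(labels == str(class_id), labels, "__rest__")
    if not (merged == "__rest__").any():
        raise ValueError("discrimination needs at least two classes")
    return class_component_plane(bmus, merged, grid, "__rest__")


def discrimination_score(
    plane: np.ndarray,
    bmus,
    labels,
    grid: GridSpec,
    class_id: str,
    normalise: bool = False,
) -> float:
    """Signed marker score of one variable for one class.

    ``index(class) - index(merged complement)``; for two classes this is
    simply ``index(A) - index(B)`` and is antisymmetric in the classes.
    ``normalise=True`` divides each index by the mass of its class plane,
    which compensates for class regions of very different size.
    """
    q = class_component_plane(bmus, labels, grid, class_id)
    q_rest = _merged_complement_plane(bmus, labels, grid, class_id)
    idx_a = somdi_index(plane, q)
    idx_b = somdi_index(plane, q_rest)
    if normalise:
        idx_a = idx_a / q.sum() if q.sum() > 0 else 0.0
        idx_b = idx_b / q_rest.sum() if q_rest.sum() > 0 else 0.0
    return idx_a - idx_b


def rank_variables(scores) -> np.ndarray:
    """Variable indices in descending score order; equal scores keep their
    input order (stable sort)."""
    scores = np.asarray(scores, dtype=float)
    return np.argsort(-scores, kind="stable")


def _count_regions(F: np.ndarray, grid: GridSpec) -> int:
    """Connected map regions of strictly dominant class.

    Cells whose top class fraction is tied count as boundaries, so two
    islands of the same class joined only by tie corridors stay separate.
    """
    top = F.max(axis=1)
    dominant = F.argmax(axis=1)
    strict = (F == top[:, None]).sum(axis=1) == 1
    neighbours = grid.neighbour_lists()
    seen = np.zeros(grid.n_cells, dtype=bool)
    regions = 0
    for start in range(grid.n_cells):
        if seen[start] or not strict[start]:
            continue
        regions += 1
        stack = [start]
        seen[start] = True
        while stack:
            c = stack.pop()
            for n in neighbours[c]:
                if not seen[n] and strict[n] and dominant[n] == dominant[c]:
                    seen[n] = True
                    stack.append(n)
    return regions


def somdi_table(
    codebook: Codebook,
    bmus,
    labels,
    normalise: bool = False,
    warn_fragmented: bool = True,
) -> pd.DataFrame:
    """Per-variable SOMDI indices, discrimination scores and ranks for
    every class, as one tidy table.

    Works on supervised or unsupervised maps; on an unsupervised map the
    scores are only meaningful when the class of interest dominates the
    layout, so a warning is raised when the dominant-class regions are
    heavily fragmented (more than three regions per class).
    """
    labels = np.asarray(labels)
    cm = class_map(bmus, labels, codebook.grid)
    class_ids = cm.class_ids
    if len(class_ids) < 2:
        raise ValueError("SOMDI discrimination needs at least two classes")
    if warn_fragmented:
        n_regions = _count_regions(cm.F, codebook.grid)
        if n_regions > 3 * len(class_ids):
            warnings.warn(
                f"class map is fragmented ({n_regions} regions for "
                f"{len(class_ids)} classes); SOMDI scores on this map may be unreliable"
            )
    planes = np.stack([component_plane(codebook, j) for j in range(codebook.n_vars)])
    rows = {}
    for cid in class_ids:
        q = cm.F[:, class_ids.index(cid)]
        q_rest = _merged_complement_plane(bmus, labels, codebook.grid, cid)
        idx = planes @ q
        idx_rest = planes @ q_rest
        if normalise:
            idx = idx / q.sum() if q.sum() > 0 else np.zeros_like(idx)
            idx_rest = idx_rest / q_rest.sum() if q_rest.sum() > 0 else np.zeros_like(idx_rest)
        score = idx - idx_rest
        order = rank_variables(score)
        rank = np.empty_like(order)
        rank[order] = np.arange(1, len(order) + 1)
        rows[f"index_{cid}"] = idx
        rows[f"score_{cid}"] = score
        rows[f"rank_{cid}"] = rank
    return pd.DataFrame(rows, index=list(codebook.var_ids))
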