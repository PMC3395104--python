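"""Supervised SOMs: class-membership planes trained alongside the
variable planes, with an adjustable class weight, plus test-set
prediction and %CC (percentage correctly classified).

Supervision appends one plane per class to the map.  Each training sample
carries a membership vector (1 for its class, 0 for the others); the BMU
search uses a weighted combination of variable-block and class-block
distances, so a class weight ``w`` of 0 reproduces the unsupervised map
exactly while ``w`` near 1 forces the samples into their class structure
(and can badly overfit — always check a held-out %CC).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .core import Codebook, Dataset, TrainingSchedule, default_schedule, init_random, _sgd_loop
from .grid import GridSpec
from .views import assign_bmus, class_map, ClassMap

__all__ = [
    "encode_classes",
    "train_supervised",
    "SupervisedSOM",
    "predict",
    "ClassificationResult",
    "percent_cc",
]


def encode_classes(labels, class_ids: list[str]) -> np.ndarray:
    """Per-sample class-membership rows.

    Crisp labels become one-hot rows; a 2-D array of fuzzy memberships in
    [0, 1] is validated and passed through unchanged.
    """
    arr = np.asarray(labels)
    if arr.ndim == 2:
        if arr.shape[1] != len(class_ids):
            raise ValueError("membership matrix width does not match class_ids")
        arr = arr.astype(float)
        if arr.min() < 0 or arr.max() > 1:
            raise ValueError("fuzzy memberships must lie in [0, 1]")
        return arr
    C = np.zeros((arr.shape[0], len(class_ids)))
    lookup = {str(c): k for k, c in enumerate(class_ids)}
    for i, lab in enumerate(arr):
        key = str(lab)
        if key not in lookup:
            raise ValueError(f"label {key!r} not among class_ids {class_ids}")
        C[i, lookup[key]] = 1.0
    return C


def _mean_sq_pairwise(M: np.ndarray) -> float:
    """Mean squared pairwise Euclidean distance between rows (block
    normaliser; 0 for a single row or identical rows)."""
    if M.shape[0] < 2:
        return 0.0
    return float((pdist(M, metric="sqeuclidean")).mean())


@dataclass
class SupervisedSOM:
    """A trained supervised map: variable codebook + class planes."""

    codebook: Codebook
    class_planes: np.ndarray  # (n_cells, n_classes) in [0, 1]
    class_ids: list[str]
    class_weight: float
    training_bmus: np.ndarray
    training_labels: np.ndarray
    schedule: TrainingSchedule

    @property
    def grid(self) -> GridSpec:
        return self.codebook.grid

    def class_map(self) -> ClassMap:
        return class_map(self.training_bmus, self.training_labels, self.grid, self.class_ids)

    def predict(self, X_test) -> "ClassificationResult":
        return predict(self.codebook, self.training_bmus, self.training_labels, X_test, self.class_ids)


def train_supervised(
    data: Dataset,
    labels,
    grid: GridSpec | None = None,
    schedule: TrainingSchedule | None = None,
    class_weight: float = 0.5,
    class_ids: list[str] | None = None,
) -> SupervisedSOM:
    """Train a SOM on the joint [variables | class planes] representation.

    The BMU distance is ``(1 - w) * d2_X / nu_X + w * d2_C / nu_C`` where
    the normalisers ``nu`` are the mean squared pairwise sample distances
    of each block, fixed before training, so ``w = 0.5`` means the two
    blocks carry equal importance.  Updates apply the same neighbourhood
    kernel to both blocks; class planes are clipped back to [0, 1] after
    each update.  With ``w = 0`` the variable codebook is bitwise
    identical to the unsupervised map for the same seed and schedule.
    """
    w = float(class_weight)
    if not (0.0 <= w <= 1.0):
        raise ValueError("class_weight must lie in [0, 1]")
    labels = np.asarray(labels)
    if labels.shape[0] != data.n_samples:
        raise ValueError("labels are not aligned with data")
    if class_ids is None:
        class_ids = sorted(set(str(l) for l in labels))
    if len(class_ids) < 2 and w > 0:
        warnings.warn("single-class supervision is degenerate; the class block carries no contrast")
    if grid is None:
        from .grid import default_map_size

        grid = default_map_size(data.n_samples)
    if schedule is None:
        schedule = default_schedule(grid, data.n_samples)

    C = encode_classes(labels, class_ids)
    X_joint = np.hstack([data.X, C])
    p = data.n_vars
    k = len(class_ids)

    W0 = init_random(grid, data, schedule.seed).W
    rng_c = np.random.default_rng((schedule.seed, 1))  # separate stream: keeps the X init identical
    C0 = rng_c.random((grid.n_cells, k))
    W_joint = np.hstack([W0, C0])

    if w == 0.0:
        scales = [1.0, 0.0]  # exact unsupervised reduction, down to float rounding
    else:
        nu_x = _mean_sq_pairwise(data.X)
        nu_c = _mean_sq_pairwise(C)
        scales = [(1.0 - w) / (nu_x if nu_x > 0 else 1.0), w / (nu_c if nu_c > 0 else 1.0)]

    _sgd_loop(
        X_joint,
        W_joint,
        block_slices=[slice(0, p), slice(p, p + k)],
        block_scales=scales,
        D=grid.distance_matrix(),
        schedule=schedule,
        clip_slice=slice(p, p + k),
        qe_slice=slice(0, p),
    )
    codebook = Codebook(W_joint[:, :p], grid, var_ids=list(data.var_ids))
    bmus = assign_bmus(codebook, data)
    return SupervisedSOM(
        codebook=codebook,
        class_planes=W_joint[:, p:],
        class_ids=list(class_ids),
        class_weight=w,
        training_bmus=bmus,
        training_labels=labels,
        schedule=schedule,
    )


@dataclass
class ClassificationResult:
    """Per-sample class fractions (rows sum to 1) and the apportioned %CC
    helper.  A sample whose BMU sits on a class boundary contributes its
    fraction on the true class, e.g. 0.5 for a two-way tie."""

    fractions: pd.DataFrame  # index: sample ids, columns: class ids
    bmus: np.ndarray

    @property
    def class_ids(self) -> list[str]:
        return list(self.fractions.columns)

    def hard_calls(self) -> pd.Series:
        """Majority class per sample (ties to the first class id)."""
        return self.fractions.idxmax(axis=1)


def predict(
    codebook: Codebook,
    training_bmus: np.ndarray,
    training_labels,
    X_test,
    class_ids: list[str] | None = None,
) -> ClassificationResult:
    """Classify test samples by where they slot into the trained map.

    Each test sample's BMU is found with the variable block only (class
    membership is unknown at prediction time); its class fractions are the
    class-map mixture at that cell, so a BMU equidistant between a class-A
    and a class-B training BMU is assigned 50% to each.
    """
    if isinstance(X_test, Dataset):
        sample_ids = X_test.sample_ids
        X = X_test.X
    else:
        X = np.asarray(X_test, dtype=float)
        sample_ids = [f"t{i}" for i in range(X.shape[0])]
    if X.shape[0] == 0:
        cm = class_map(training_bmus, training_labels, codebook.grid, class_ids)
        return ClassificationResult(
            pd.DataFrame(np.zeros((0, len(cm.class_ids))), columns=cm.class_ids),
            np.zeros(0, dtype=int),
        )
    cm = class_map(training_bmus, training_labels, codebook.grid, class_ids)
    test_bmus = assign_bmus(codebook, X)
    frac = cm.F[test_bmus]
    return ClassificationResult(
        pd.DataFrame(frac, index=sample_ids, columns=cm.class_ids), test_bmus
    )


def percent_cc(result: ClassificationResult, true_labels) -> float:
    """%CC with boundary apportioning: 100 times the mean fraction each
    sample's prediction places on its true class."""
    true_labels = [str(l) for l in np.asarray(true_labels)]
    if len(true_labels) != result.fractions.shape[0]:
        raise ValueError("true_labels not aligned with predictions")
    if len(true_labels) == 0:
        raise ValueError("cannot compute %CC on an empty result")
    cols = result.class_ids
    total = 0.0
    for i, lab in enumerate(true_labels):
        if lab in cols:
            total += result.fractions.iloc[i][lab]
    return 100.0 * total / len(true_labels)
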