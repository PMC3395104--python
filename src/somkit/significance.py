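"""Marker significance by map reformation.

A single SOM is a stochastic object: a variable can look like a marker on
one map and not on another.  Reforming the map R times from fresh random
starting points and counting how often a variable's discrimination score
is positive gives a simple stability criterion: a variable positive in
all R reforms is a stable marker with confidence 1 - 1/R (99% at R = 100),
while a non-informative variable flips sign roughly half the time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Dataset, TrainingSchedule
from .grid import GridSpec
from .somdi import somdi_table
from .supervised import train_supervised

__all__ = ["StabilityResult", "marker_stability"]


@dataclass
class StabilityResult:
    """Per-variable sign-stability counts over R map reformations."""

    table: pd.DataFrame  # columns: positives, R, stable, confidence
    class_id: str
    R: int
    base_seed: int

    @property
    def stable_variables(self) -> list[str]:
        return list(self.table.index[self.table["stable"]])


def _one_reform(
    data: Dataset,
    labels,
    class_id: str,
    grid: GridSpec,
    schedule: TrainingSchedule,
    class_weight: float,
    seed: int,
) -> np.ndarray:
    sched = TrainingSchedule(
        T=schedule.T,
        alpha0=schedule.alpha0,
        alphaT=schedule.alphaT,
        sigma0=schedule.sigma0,
        sigmaT=schedule.sigmaT,
        decay=schedule.decay,
        seed=seed,
    )
    som = train_supervised(data, labels, grid=grid, schedule=sched, class_weight=class_weight)
    table = somdi_table(som.codebook, som.training_bmus, som.training_labels, warn_fragmented=False)
    return (table[f"score_{class_id}"].to_numpy() > 0).astype(int)


def marker_stability(
    data: Dataset,
    labels,
    class_id: str,
    R: int = 100,
    base_seed: int = 0,
    grid: GridSpec | None = None,
    schedule: TrainingSchedule | None = None,
    class_weight: float = 0.5,
    n_jobs: int = 1,
) -> StabilityResult:
    """Count, per variable, in how many of R reformed maps it scores as a
    positive marker for ``class_id``.

    Each reform trains a fresh supervised map from random initialisation
    with seed ``base_seed + i`` and scores all variables with SOMDI.  A
    variable is *stable* when its score is strictly positive in every
    reform; the associated confidence is ``1 - 1/R``.  Reforms are
    independent given their seeds, so the result does not depend on
    ``n_jobs`` or execution order.
    """
    if R < 1:
        raise ValueError("R must be at least 1")
    if R < 20:
        warnings.warn(
            f"R={R} gives at most {1 - 1 / R:.0%} confidence; "
            "around 100 reforms are recommended"
        )
    class_id = str(class_id)
    labels = np.asarray(labels)
    if class_id not in set(str(l) for l in labels):
        raise ValueError(f"class {class_id!r} not present among labels")
    if grid is None:
        from .grid import default_map_size

        grid = default_map_size(data.n_samples)
    if schedule is None:
        from .core import default_schedule

        schedule = default_schedule(grid, data.n_samples)

    seeds = [base_seed + i for i in range(R)]
    if n_jobs == 1:
        results = [
            _one_reform(data, labels, class_id, grid, schedule, class_weight, s) for s in seeds
        ]
    else:
        from joblib import Parallel, delayed

        results = Parallel(n_jobs=n_jobs)(
            delayed(_one_reform)(data, labels, class_id, grid, schedule, class_weight, s)
            for s in seeds
        )
    positives = np.sum(results, axis=0)
    stable = positives == R
    confidence = np.where(stable, 1.0 - 1.0 / R, 0.0)
    table = pd.DataFrame(
        {
            "positives": positives,
            "R": R,
            "stable": stable,
            "confidence": confidence,
        },
        index=list(data.var_ids),
    )
    return StabilityResult(table=table, class_id=class_id, R=R, base_seed=base_seed)
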