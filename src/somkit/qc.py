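"""One-class SOM monitoring for multivariate statistical process control.

A map trained only on Normal Operating Conditions (NOC) samples describes
the in-control region of the process.  Any new sample always has a BMU —
the map cannot refuse it — so the in/out-of-control decision rests on how
*well* the sample fits: its grid of distances to every cell, summarised
as a scalar fit statistic and compared with a control limit calibrated on
the NOC samples themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .core import Codebook, Dataset, TrainingSchedule, default_schedule, train
from .grid import GridSpec

__all__ = ["QCModel", "fit_noc", "distance_grid", "classify_in_control", "monitor"]


@dataclass
class QCModel:
    """A fitted NOC model: codebook, fit statistic and control limit."""

    codebook: Codebook
    statistic: str  # "min" or "mean-k"
    k: int
    limit: float
    percentile: float
    noc_stats: np.ndarray
    schedule: TrainingSchedule = None

    @property
    def grid(self) -> GridSpec:
        return self.codebook.grid


def _stat(model_stat: str, k: int, d: np.ndarray) -> float:
    if model_stat == "min":
        return float(d.min())
    if model_stat == "mean-k":
        kk = min(k, d.size)
        return float(np.sort(d)[:kk].mean())
    raise ValueError(f"unknown statistic {model_stat!r}")


def fit_noc(
    X_noc,
    grid: GridSpec | None = None,
    schedule: TrainingSchedule | None = None,
    percentile: float = 95.0,
    statistic: str = "min",
    k: int = 5,
    seed: int = 0,
    calibration: str = "loo",
) -> QCModel:
    """Fit the one-class model: train a SOM on the NOC window and
    calibrate the control limit.

    The fit statistic of a sample is its distance to the nearest cell
    (``statistic="min"``, default) or the mean of its ``k`` smallest cell
    distances (``"mean-k"``, more robust to a single stray cell).  The
    control limit is the given percentile (default 95) of the NOC
    samples' statistics, so roughly ``100 - percentile`` percent of
    future in-control samples should be flagged.

    ``calibration="loo"`` (default) computes each NOC sample's statistic
    against a map trained with that sample left out, which mimics how
    unseen samples are scored; ``"resubstitution"`` scores each sample on
    the full map, which is cheaper but badly optimistic whenever the map
    has enough cells to memorise every NOC sample, and then under-covers
    genuine in-control data.
    """
    data = X_noc if isinstance(X_noc, Dataset) else Dataset(np.asarray(X_noc, dtype=float))
    if data.n_samples < 5:
        raise ValueError("NOC model needs at least 5 samples")
    if not (0.0 <= percentile <= 100.0):
        raise ValueError("percentile must be in [0, 100]")
    if statistic not in ("min", "mean-k"):
        raise ValueError("statistic must be 'min' or 'mean-k'")
    if calibration not in ("loo", "resubstitution"):
        raise ValueError("calibration must be 'loo' or 'resubstitution'")
    if grid is None:
        from .grid import default_map_size

        grid = default_map_size(data.n_samples)
    if schedule is None:
        schedule = default_schedule(grid, data.n_samples, seed=seed)
    result = train(data, grid=grid, schedule=schedule)
    if calibration == "loo":
        stats = np.empty(data.n_samples)
        for i in range(data.n_samples):
            rest = Dataset(np.delete(data.X, i, axis=0), var_ids=list(data.var_ids))
            sub = train(rest, grid=grid, schedule=schedule)
            d = np.linalg.norm(sub.codebook.W - data.X[i], axis=1)
            stats[i] = _stat(statistic, k, d)
    else:
        D = cdist(data.X, result.codebook.W)
        stats = np.array([_stat(statistic, k, row) for row in D])
    # Weibull (n+1) plotting position: with a small calibration set the
    # default percentile interpolation is optimistic about the upper tail,
    # inflating the false-alarm rate; this convention makes the expected
    # exceedance of a fresh in-control sample close to (100 - percentile)%.
    limit = float(np.percentile(stats, percentile, method="weibull"))
    return QCModel(
        codebook=result.codebook,
        statistic=statistic,
        k=k,
        limit=limit,
        percentile=percentile,
        noc_stats=stats,
        schedule=schedule,
    )


def distance_grid(model: QCModel, x) -> np.ndarray:
    """Per-cell Euclidean distances of one sample to the NOC map; low
    values somewhere on the grid mean the sample resembles the NOC
    region, uniformly high values mean it fits nowhere."""
    x = np.asarray(x, dtype=float)
    if x.shape != (model.codebook.n_vars,):
        raise ValueError(f"sample has shape {x.shape}, expected ({model.codebook.n_vars},)")
    if not np.isfinite(x).all():
        raise ValueError("sample contains non-finite values")
    return np.linalg.norm(model.codebook.W - x, axis=1)


def classify_in_control(model: QCModel, x) -> tuple[bool, float]:
    """In/out-of-control decision for one sample.

    Returns ``(in_control, statistic)``: the sample is in control when
    its fit statistic does not exceed the calibrated control limit.
    """
    d = distance_grid(model, x)
    stat = _stat(model.statistic, model.k, d)
    return stat <= model.limit, stat


def monitor(model: QCModel, X, timestamps=None) -> pd.DataFrame:
    """Run a batch of samples through the model.

    Returns one row per sample: timestamp (if given), fit statistic,
    control limit and the in-control flag.
    """
    data = X if isinstance(X, Dataset) else Dataset(np.asarray(X, dtype=float))
    D = cdist(data.X, model.codebook.W)
    stats = np.array([_stat(model.statistic, model.k, row) for row in D])
    out = pd.DataFrame(
        {
            "statistic": stats,
            "limit": model.limit,
            "in_control": stats <= model.limit,
        },
        index=data.sample_ids,
    )
    if timestamps is not None:
        out.insert(0, "timestamp", np.asarray(timestamps))
    return out
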