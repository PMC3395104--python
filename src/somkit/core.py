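"""Codebook initialisation, BMU search and iterative SOM training.

The map is trained with the classical online (one-sample-at-a-time)
algorithm: each iteration draws a training sample uniformly with
replacement, finds its best matching unit (BMU) and pulls the weight
vectors of the BMU and its map neighbours towards the sample.  Both the
learning rate ``alpha`` and the neighbourhood width ``sigma`` decay over
the run, so the map first organises globally and then fine-tunes locally.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .grid import GridSpec

__all__ = [
    "Dataset",
    "Codebook",
    "TrainingSchedule",
    "TrainResult",
    "init_random",
    "init_pca",
    "find_bmu",
    "train",
    "missed_sample_probability",
    "quantization_error",
    "default_schedule",
]


@dataclass
class Dataset:
    """A numeric sample-by-variable matrix with identifiers.

    ``X`` holds preprocessed intensities (spectral buckets, wavelengths or
    peak areas): one row per sample, one column per variable.  Missing or
    non-finite values are rejected at construction.
    """

    X: np.ndarray
    sample_ids: list[str] = field(default=None)
    var_ids: list[str] = field(default=None)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[0] < 1 or self.X.shape[1] < 1:
            raise ValueError("X must be a non-empty 2-D matrix")
        if not np.isfinite(self.X).all():
            raise ValueError("X contains non-finite values")
        n, p = self.X.shape
        if self.sample_ids is None:
            self.sample_ids = [f"s{i}" for i in range(n)]
        if self.var_ids is None:
            self.var_ids = [f"v{j}" for j in range(p)]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.var_ids = [str(v) for v in self.var_ids]
        if len(self.sample_ids) != n or len(self.var_ids) != p:
            raise ValueError("identifier lengths do not match matrix shape")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_vars(self) -> int:
        return self.X.shape[1]


@dataclass
class Codebook:
    """Per-cell weight vectors: row c is the 'spectrum' behind cell c.

    Column j, reshaped onto the grid, is the (unscaled) component plane of
    variable j.
    """

    W: np.ndarray
    grid: GridSpec
    var_ids: list[str] = None

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        if self.W.ndim != 2:
            raise ValueError("W must be 2-D")
        if self.W.shape[0] != self.grid.n_cells:
            raise ValueError(
                f"codebook has {self.W.shape[0]} rows but grid has {self.grid.n_cells} cells"
            )
        if not np.isfinite(self.W).all():
            raise ValueError("codebook contains non-finite entries")
        if self.var_ids is None:
            self.var_ids = [f"v{j}" for j in range(self.W.shape[1])]

    @property
    def n_cells(self) -> int:
        return self.W.shape[0]

    @property
    def n_vars(self) -> int:
        return self.W.shape[1]


@dataclass(frozen=True)
class TrainingSchedule:
    """Iteration count, learning-rate and neighbourhood-width decay.

    ``alpha`` (learning rate) decays from ``alpha0`` to ``alphaT`` and the
    neighbourhood width ``sigma`` from ``sigma0`` to ``sigmaT``, either
    linearly or exponentially in the iteration number.  ``seed`` drives the
    sample-drawing stream, making training fully reproducible.
    """

    T: int
    alpha0: float = 0.5
    alphaT: float = 0.01
    sigma0: float = 3.0
    sigmaT: float = 0.5
    decay: str = "linear"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.T < 1:
            raise ValueError("iteration count T must be at least 1")
        if not (0 < self.alphaT <= self.alpha0 <= 1):
            raise ValueError("need 0 < alphaT <= alpha0 <= 1")
        if not (0 <= self.sigmaT <= self.sigma0):
            raise ValueError("need 0 <= sigmaT <= sigma0")
        if self.decay not in ("linear", "exponential"):
            raise ValueError("decay must be 'linear' or 'exponential'")

    def alpha(self, t: int) -> float:
        return self._interp(self.alpha0, self.alphaT, t)

    def sigma(self, t: int) -> float:
        return self._interp(self.sigma0, self.sigmaT, t)

    def _interp(self, start: float, end: float, t: int) -> float:
        if self.T == 1:
            return start
        frac = t / (self.T - 1)
        if self.decay == "linear":
            return start + (end - start) * frac
        if end == 0 or start == 0:  # exponential decay needs positive endpoints
            return start + (end - start) * frac
        return start * (end / start) ** frac

    def to_dict(self) -> dict:
        return {
            "T": self.T,
            "alpha0": self.alpha0,
            "alphaT": self.alphaT,
            "sigma0": self.sigma0,
            "sigmaT": self.sigmaT,
            "decay": self.decay,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrainingSchedule":
        return cls(
            T=int(d["T"]),
            alpha0=float(d["alpha0"]),
            alphaT=float(d["alphaT"]),
            sigma0=float(d["sigma0"]),
            sigmaT=float(d["sigmaT"]),
            decay=d["decay"],
            seed=int(d["seed"]),
        )


def default_schedule(grid: GridSpec, n_samples: int, seed: int = 0, T: int | None = None) -> TrainingSchedule:
    """Default schedule: many iterations per sample, wide-to-narrow kernel.

    The iteration count is ``max(10000, 100 * n_samples)`` so that the
    chance of any sample never being drawn is negligible; the initial
    neighbourhood width spans a quarter of the map's longer side.
    """
    if T is None:
        T = max(10_000, 100 * n_samples)
    sigma0 = max(1.0, max(grid.n_rows, grid.n_cols) / 4)
    return TrainingSchedule(T=T, sigma0=sigma0, sigmaT=0.5, alpha0=0.5, alphaT=0.01, seed=seed)


@dataclass
class TrainResult:
    """Trained codebook plus the quantization-error log."""

    codebook: Codebook
    log: "list[tuple[int, float]]"  # (iteration, quantization error) checkpoints


def init_random(grid: GridSpec, data: Dataset, seed: int) -> Codebook:
    """Random codebook: each cell vector drawn per-variable uniform on the
    observed [min, max] of that variable.  Constant variables stay constant."""
    rng = np.random.default_rng(seed)
    lo = data.X.min(axis=0)
    hi = data.X.max(axis=0)
    W = lo + (hi - lo) * rng.random((grid.n_cells, data.n_vars))
    return Codebook(W, grid, var_ids=list(data.var_ids))


def init_pca(grid: GridSpec, data: Dataset) -> Codebook:
    """Codebook laid out on the plane of the first two principal axes.

    The cell at fractional map position (u, v) in [-1, 1]^2 receives
    ``mean + u*s1*p1 + v*s2*p2`` where p1, p2 are the first two loading
    vectors of the column-centred data and s1, s2 the corresponding
    standard-deviation scales.  Rank-deficient data falls back to a
    rank-1 line with a warning.
    """
    if data.n_samples < 3:
        raise ValueError("PCA initialisation needs at least 3 samples")
    if data.n_vars < 2:
        raise ValueError("PCA initialisation needs at least 2 variables")
    mean = data.X.mean(axis=0)
    Xc = data.X - mean
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    scale = s / math.sqrt(max(data.n_samples - 1, 1))
    tol = max(Xc.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    rank = int((s > tol).sum())
    if rank < 2:
        warnings.warn("data rank < 2: PCA initialisation falls back to a rank-1 line")
    rows, cols = np.divmod(np.arange(grid.n_cells), grid.n_cols)
    u = 2.0 * rows / (grid.n_rows - 1) - 1.0 if grid.n_rows > 1 else np.zeros(grid.n_cells)
    v = 2.0 * cols / (grid.n_cols - 1) - 1.0 if grid.n_cols > 1 else np.zeros(grid.n_cells)
    W = np.tile(mean, (grid.n_cells, 1))
    if rank >= 1:
        W += np.outer(u, scale[0] * Vt[0])
    if rank >= 2:
        W += np.outer(v, scale[1] * Vt[1])
    return Codebook(W, grid, var_ids=list(data.var_ids))


def find_bmu(codebook: Codebook, x: np.ndarray) -> int:
    """Best matching unit: the cell with minimum Euclidean distance to x.

    Ties are broken by the lowest cell index.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (codebook.n_vars,):
        raise ValueError(f"sample has shape {x.shape}, expected ({codebook.n_vars},)")
    if not np.isfinite(x).all():
        raise ValueError("sample contains non-finite values")
    diff = codebook.W - x
    return int(np.argmin(np.einsum("ij,ij->i", diff, diff)))


def _kernel(d_row: np.ndarray, sigma: float) -> np.ndarray:
    """Truncated Gaussian neighbourhood kernel over lattice distances.

    h(d, sigma) = exp(-d^2 / (2 sigma^2)) for d <= ceil(3 sigma), else 0.
    At sigma = 0 only the BMU itself (d = 0) is updated.
    """
    if sigma <= 0:
        return (d_row == 0).astype(float)
    h = np.exp(-(d_row.astype(float) ** 2) / (2.0 * sigma * sigma))
    h[d_row > math.ceil(3 * sigma)] = 0.0
    return h


def _sgd_loop(
    X: np.ndarray,
    W: np.ndarray,
    block_slices: list[slice],
    block_scales: list[float],
    D: np.ndarray,
    schedule: TrainingSchedule,
    clip_slice: slice | None = None,
    checkpoints: int = 10,
    qe_slice: slice | None = None,
) -> list[tuple[int, float]]:
    """Shared online-update loop; W is modified in place.

    BMU distance is ``sum_k scale_k * ||x_k - W_k||^2`` over the column
    blocks; the update applies the same kernel to every column.  Blocks
    with scale 0 do not influence the BMU but are still updated (this is
    what makes zero-weight supervision bitwise-identical to unsupervised
    training on the variable block).
    """
    rng = np.random.default_rng(schedule.seed)
    n = X.shape[0]
    T = schedule.T
    qe_sl = qe_slice if qe_slice is not None else slice(0, X.shape[1])
    log: list[tuple[int, float]] = []
    check_every = max(1, T // max(checkpoints, 1))
    for t in range(T):
        i = int(rng.integers(n))
        x = X[i]
        d2 = np.zeros(W.shape[0])
        for sl, sc in zip(block_slices, block_scales):
            diff = x[sl] - W[:, sl]
            d2 += sc * np.einsum("ij,ij->i", diff, diff)
        b = int(np.argmin(d2))
        sigma = schedule.sigma(t)
        alpha = schedule.alpha(t)
        d_row = D[b]
        active = np.flatnonzero(d_row <= math.ceil(3 * sigma)) if sigma > 0 else np.array([b])
        h = _kernel(d_row[active], sigma)
        W[active] += (alpha * h)[:, None] * (x - W[active])
        if clip_slice is not None:
            W[active, clip_slice] = np.clip(W[active, clip_slice], 0.0, 1.0)
        if (t + 1) % check_every == 0 or t == T - 1:
            log.append((t + 1, _qe(W[:, qe_sl], X[:, qe_sl])))
    return log


def _qe(W: np.ndarray, X: np.ndarray) -> float:
    from scipy.spatial.distance import cdist

    return float(cdist(X, W).min(axis=1).mean())


def train(
    data: Dataset,
    grid: GridSpec | None = None,
    schedule: TrainingSchedule | None = None,
    init: Codebook | str = "random",
) -> TrainResult:
    """Train an unsupervised SOM.

    Parameters
    ----------
    data
        Training samples.
    grid
        Map geometry; defaults to roughly three cells per sample.
    schedule
        Iteration count and decay parameters; a sensible default is built
        from the grid and sample count when omitted.
    init
        ``"random"``, ``"pca"`` or a pre-built :class:`Codebook`.

    Returns
    -------
    TrainResult
        The trained codebook and a quantization-error log, deterministic
        given ``schedule.seed``.
    """
    if grid is None:
        from .grid import default_map_size

        grid = default_map_size(data.n_samples)
    if schedule is None:
        schedule = default_schedule(grid, data.n_samples)
    if isinstance(init, str):
        if init == "random":
            init = init_random(grid, data, schedule.seed)
        elif init == "pca":
            init = init_pca(grid, data)
        else:
            raise ValueError(f"unknown init {init!r}")
    if init.grid.to_dict() != grid.to_dict():
        raise ValueError("initial codebook grid does not match requested grid")
    W = init.W.copy()
    D = grid.distance_matrix()
    log = _sgd_loop(
        data.X,
        W,
        block_slices=[slice(0, data.n_vars)],
        block_scales=[1.0],
        D=D,
        schedule=schedule,
    )
    return TrainResult(Codebook(W, grid, var_ids=list(data.var_ids)), log)


def missed_sample_probability(N: int, T: int) -> float:
    """Probability a given sample is never drawn in T uniform draws with
    replacement from N samples: ((N - 1) / N) ** T, in log space."""
    if N < 1:
        raise ValueError("N must be a positive integer")
    if T < 0:
        raise ValueError("T must be non-negative")
    if T == 0:
        return 1.0
    if N == 1:
        return 0.0
    return float(math.exp(T * math.log1p(-1.0 / N)))


def quantization_error(codebook: Codebook, data: Dataset) -> float:
    """Mean Euclidean distance from each sample to its BMU."""
    if data.n_vars != codebook.n_vars:
        raise ValueError("variable count mismatch between data and codebook")
    return _qe(codebook.W, data.X)
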