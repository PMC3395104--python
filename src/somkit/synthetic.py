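"""Seeded synthetic data emulating four chemometric study designs.

The generators reproduce the *designs* (sample counts, factor structure,
in-control windows) of four published-style case studies — NIR spectra of
edible oils, thermal profiles of polymers, an NMR saliva study with a
2 x 16 x 3 treatment/donor/day design, and an on-line HPLC process run —
on top of simple additive-Gaussian signal models with known ground truth,
so classification, marker recovery and process monitoring can be tested
end to end without any external data.  They are pure functions of their
arguments: the same seed always yields the identical dataset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Dataset

__all__ = [
    "SyntheticData",
    "gen_oils_like",
    "gen_polymers_like",
    "gen_saliva_like",
    "gen_process_like",
    "Preprocessor",
    "preprocess",
]


@dataclass
class SyntheticData:
    """Generated matrix, its factor columns, and the generating truth."""

    data: Dataset
    factors: pd.DataFrame
    truth: dict


def _bump_profile(rng: np.random.Generator, n_vars: int) -> np.ndarray:
    """A smooth spectrum-like profile: 3-5 Gaussian bumps."""
    n_bumps = int(rng.integers(3, 6))
    x = np.arange(n_vars)
    profile = np.zeros(n_vars)
    for _ in range(n_bumps):
        centre = rng.uniform(0, n_vars)
        width = rng.uniform(0.03, 0.08) * n_vars
        amp = rng.uniform(0.5, 1.5)
        profile += amp * np.exp(-((x - centre) ** 2) / (2 * width**2))
    return profile


def _enforce_separation(means: np.ndarray, target: float) -> np.ndarray:
    """Rescale centred class means so the smallest pairwise centroid
    distance equals ``target`` exactly."""
    centred = means - means.mean(axis=0)
    dmin = np.inf
    for i in range(len(means)):
        for j in range(i + 1, len(means)):
            dmin = min(dmin, float(np.linalg.norm(centred[i] - centred[j])))
    if dmin == 0:
        raise RuntimeError("degenerate class means")  # bump draws cannot all coincide
    return means.mean(axis=0) + centred * (target / dmin)


def gen_oils_like(
    seed: int,
    n_vars: int = 100,
    noise: float = 0.15,
    separation: float = 4.0,
) -> SyntheticData:
    """Four well-separated spectral classes with the oils design:
    18 corn oils, 30 olive oils, 16 safflower oils, 8 corn margarines.

    Class means are smooth bump mixtures rescaled so the smallest
    between-class centroid distance is ``separation`` times the expected
    within-class sample-to-sample distance ``noise * sqrt(2 * n_vars)``.
    """
    rng = np.random.default_rng(seed)
    class_names = ["corn_oil", "olive_oil", "safflower_oil", "corn_margarine"]
    class_sizes = [18, 30, 16, 8]
    means = np.stack([_bump_profile(rng, n_vars) for _ in class_names])
    sigma_within = noise * np.sqrt(2.0 * n_vars)
    if noise > 0:
        means = _enforce_separation(means, separation * sigma_within)
    else:
        means = _enforce_separation(means, separation)
    labels = np.repeat(class_names, class_sizes)
    X = np.vstack(
        [
            means[k] + noise * rng.standard_normal((sz, n_vars))
            for k, sz in enumerate(class_sizes)
        ]
    )
    data = Dataset(X, sample_ids=[f"oil{i:02d}" for i in range(len(labels))])
    factors = pd.DataFrame({"class": labels}, index=data.sample_ids)
    truth = {
        "class_names": class_names,
        "class_sizes": class_sizes,
        "class_means": means,
        "noise": noise,
        "separation": separation,
    }
    return SyntheticData(data, factors, truth)


def gen_polymers_like(
    seed: int,
    n_vars: int = 60,
    noise: float = 0.2,
    type_separation: float = 8.0,
    group_separation: float = 3.0,
) -> SyntheticData:
    """Two polymer types (92 amorphous, 201 semi-crystalline) split into
    nine groups with the published counts, as a two-level hierarchy.

    Group means sit around their type mean, with the between-type
    distance larger than the between-group-within-type distances by
    construction (``type_separation`` > ``group_separation``, both in
    units of the within-group spread).
    """
    rng = np.random.default_rng(seed)
    groups = [
        ("PS", "amorphous", 35),
        ("ABS", "amorphous", 47),
        ("PCarb", "amorphous", 10),
        ("LDPE", "semi-crystalline", 56),
        ("PP", "semi-crystalline", 45),
        ("HDPE", "semi-crystalline", 30),
        ("PA6", "semi-crystalline", 20),
        ("PBT", "semi-crystalline", 10),
        ("PET", "semi-crystalline", 40),
    ]
    sigma_within = noise * np.sqrt(2.0 * n_vars)
    scale = sigma_within if noise > 0 else 1.0
    type_means = _enforce_separation(
        np.stack([_bump_profile(rng, n_vars) for _ in range(2)]),
        type_separation * scale,
    )
    type_index = {"amorphous": 0, "semi-crystalline": 1}
    group_means = []
    for _, tname, _ in groups:
        offset = rng.standard_normal(n_vars)
        offset *= group_separation * scale / np.linalg.norm(offset)
        group_means.append(type_means[type_index[tname]] + offset)
    group_means = np.stack(group_means)
    rows, glabels, tlabels = [], [], []
    for k, (gname, tname, size) in enumerate(groups):
        rows.append(group_means[k] + noise * rng.standard_normal((size, n_vars)))
        glabels += [gname] * size
        tlabels += [tname] * size
    X = np.vstack(rows)
    data = Dataset(X, sample_ids=[f"pol{i:03d}" for i in range(len(glabels))])
    factors = pd.DataFrame({"group": glabels, "type": tlabels}, index=data.sample_ids)
    truth = {
        "groups": [(g, t, s) for g, t, s in groups],
        "type_means": type_means,
        "group_means": group_means,
        "noise": noise,
    }
    return SyntheticData(data, factors, truth)


def gen_saliva_like(
    seed: int,
    n_vars: int = 100,
    treatment_effect: float = 2.0,
    donor_effect: float = 2.0,
    day_effect: float = 0.0,
    noise: float = 1.0,
    n_treatment_markers: int = 5,
    n_donor_markers: int = 3,
) -> SyntheticData:
    """The 2 x 16 x 3 saliva design: 2 treatments (mouthwash / control),
    16 donors, 3 sampling days — 96 samples, 6 per donor (3 treated).

    Treatment adds ``treatment_effect * noise`` to the planted treatment
    marker variables of treated samples; each donor adds
    ``donor_effect * noise`` to that donor's own marker variables; the
    sampling day is a dummy factor with no effect by default.  Effect
    sizes are therefore standardised (units of the noise SD).  The truth
    dict returns all planted marker indices.
    """
    rng = np.random.default_rng(seed)
    needed = n_treatment_markers + 16 * n_donor_markers
    if needed > n_vars:
        raise ValueError(f"need at least {needed} variables for disjoint marker sets")
    perm = rng.permutation(n_vars)
    treatment_markers = np.sort(perm[:n_treatment_markers])
    donor_markers = {
        f"D{d + 1:02d}": np.sort(
            perm[n_treatment_markers + d * n_donor_markers:
                 n_treatment_markers + (d + 1) * n_donor_markers]
        )
        for d in range(16)
    }
    day_markers = np.sort(perm[needed: needed + n_treatment_markers])

    donors, treatments, days = [], [], []
    for d in range(16):
        for day in range(3):
            for treat in ("mouthwash", "control"):
                donors.append(f"D{d + 1:02d}")
                days.append(f"day{day + 1}")
                treatments.append(treat)
    n = len(donors)  # 96
    X = noise * rng.standard_normal((n, n_vars))
    for i in range(n):
        if treatments[i] == "mouthwash":
            X[i, treatment_markers] += treatment_effect * noise
        X[i, donor_markers[donors[i]]] += donor_effect * noise
        if day_effect != 0.0:
            X[i, day_markers] += day_effect * noise * (int(days[i][-1]) - 2)
    data = Dataset(X, sample_ids=[f"sal{i:02d}" for i in range(n)])
    factors = pd.DataFrame(
        {"treatment": treatments, "donor": donors, "day": days}, index=data.sample_ids
    )
    truth = {
        "treatment_markers": treatment_markers,
        "donor_markers": donor_markers,
        "day_markers": day_markers,
        "treatment_effect": treatment_effect,
        "donor_effect": donor_effect,
        "day_effect": day_effect,
        "noise": noise,
    }
    return SyntheticData(data, factors, truth)


def gen_process_like(
    seed: int,
    n_samples: int = 309,
    n_peaks: int = 12,
    log_noise: float = 0.05,
    changepoint: int = 201,
    shift: float = 0.3,
    ramp: int = 10,
    total_hours: float = 105.11,
) -> SyntheticData:
    """An on-line HPLC process run: 309 time-stamped samples of 12 peak
    areas, stationary through an NOC window at samples 63-92 (1-based),
    then drifting in composition from the programmed changepoint.

    The relative composition is stationary (multiplicative log-normal
    noise) before ``changepoint``; from there the areas of four peaks
    shift by ``±shift`` (relative), ramped in over ``ramp`` samples and
    then sustained.  Raw areas are returned; square-root scaling and
    closure to a constant total are applied with :func:`preprocess`.
    """
    rng = np.random.default_rng(seed)
    base = rng.uniform(0.5, 1.5, n_peaks)
    base /= base.sum()
    totals = rng.normal(1000.0, 50.0, n_samples)
    shift_peaks = rng.choice(n_peaks, size=4, replace=False)
    delta = np.zeros(n_peaks)
    delta[shift_peaks[:2]] = shift
    delta[shift_peaks[2:]] = -shift
    X = np.empty((n_samples, n_peaks))
    for i in range(n_samples):
        comp = base * np.exp(log_noise * rng.standard_normal(n_peaks))
        if i + 1 >= changepoint:
            frac = min(1.0, (i + 1 - changepoint + 1) / ramp)
            comp = comp * (1.0 + frac * delta)
        comp /= comp.sum()
        X[i] = totals[i] * comp
    time_h = np.linspace(0.0, total_hours, n_samples)
    data = Dataset(X, sample_ids=[f"p{i + 1:03d}" for i in range(n_samples)])
    factors = pd.DataFrame({"time_h": time_h}, index=data.sample_ids)
    truth = {
        "noc_range": (63, 92),  # 1-based, inclusive
        "changepoint": changepoint,  # 1-based: first drifted sample
        "shift_peaks": shift_peaks,
        "shift": shift,
        "ramp": ramp,
        "base_composition": base,
        "log_noise": log_noise,
    }
    return SyntheticData(data, factors, truth)


_STEPS = ("sqrt", "centre", "close_to_total", "minmax")


class Preprocessor:
    """An ordered preprocessing pipeline whose data-dependent parameters
    (column means for centring, column ranges for min-max scaling) are
    fitted once and frozen, so test or monitoring data is transformed
    exactly as the training data was.

    Steps: ``sqrt`` (requires non-negative data), ``centre`` (column mean
    subtraction), ``close_to_total`` (each row rescaled to sum to
    ``total``), ``minmax`` (per-column scaling to [0, 1]).
    """

    def __init__(self, steps, total: float = 100.0):
        steps = list(steps)
        for s in steps:
            if s not in _STEPS:
                raise ValueError(f"unknown preprocessing step {s!r}; choose from {_STEPS}")
        self.steps = steps
        self.total = float(total)
        self.params: dict[int, dict] = {}
        self.fitted = False

    def fit(self, data: Dataset) -> "Preprocessor":
        self.params = {}
        self._apply(data.X, fit=True)
        self.fitted = True
        return self

    def transform(self, data: Dataset) -> Dataset:
        if not self.fitted:
            raise RuntimeError("Preprocessor must be fitted before transform")
        X = self._apply(data.X, fit=False)
        return Dataset(X, sample_ids=list(data.sample_ids), var_ids=list(data.var_ids))

    def fit_transform(self, data: Dataset) -> Dataset:
        return self.fit(data).transform(data)

    def _apply(self, X: np.ndarray, fit: bool) -> np.ndarray:
        X = np.array(X, dtype=float)
        for k, step in enumerate(self.steps):
            if step == "sqrt":
                if (X < 0).any():
                    raise ValueError("sqrt step requires non-negative data")
                X = np.sqrt(X)
            elif step == "centre":
                if fit:
                    self.params[k] = {"means": X.mean(axis=0)}
                X = X - self.params[k]["means"]
            elif step == "close_to_total":
                sums = X.sum(axis=1, keepdims=True)
                if (sums == 0).any():
                    raise ValueError("cannot close rows that sum to zero")
                X = X * (self.total / sums)
            elif step == "minmax":
                if fit:
                    self.params[k] = {"lo": X.min(axis=0), "hi": X.max(axis=0)}
                lo, hi = self.params[k]["lo"], self.params[k]["hi"]
                span = np.where(hi > lo, hi - lo, 1.0)
                X = (X - lo) / span
        return X

    def to_dict(self) -> dict:
        return {
            "steps": self.steps,
            "total": self.total,
            "fitted": self.fitted,
            "params": {
                str(k): {name: np.asarray(v).tolist() for name, v in p.items()}
                for k, p in self.params.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Preprocessor":
        pp = cls(d["steps"], total=d["total"])
        pp.params = {
            int(k): {name: np.asarray(v, dtype=float) for name, v in p.items()}
            for k, p in d.get("params", {}).items()
        }
        pp.fitted = bool(d.get("fitted", False))
        return pp


def preprocess(data: Dataset, steps, total: float = 100.0) -> tuple[Dataset, Preprocessor]:
    """Fit the pipeline on ``data``, transform it, and return both the
    transformed dataset and the frozen pipeline for later reuse."""
    pp = Preprocessor(steps, total=total)
    return pp.fit_transform(data), pp
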