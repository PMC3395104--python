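"""Data ingest and model persistence.

Matrices travel as CSV/TSV: header row of variable ids, first column the
sample id, optional categorical factor columns pulled out by name.
Models are stored in a single self-describing JSON container that
round-trips losslessly (bit-identical on save -> load -> save).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import Codebook, Dataset, TrainingSchedule
from .grid import GridSpec
from .qc import QCModel
from .supervised import SupervisedSOM
from .synthetic import Preprocessor

__all__ = [
    "read_matrix",
    "write_matrix",
    "save_model",
    "load_model",
    "ModelIntegrityError",
]

FORMAT_VERSION = "1.0"


class ModelIntegrityError(Exception):
    """Raised when a model file is corrupt, truncated or incompatible."""


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_matrix(path, factor_columns=()) -> tuple[Dataset, pd.DataFrame]:
    """Read a sample x variable matrix with optional factor columns.

    The delimiter is sniffed from the extension (``.tsv``/``.tab`` for
    tabs, comma otherwise).  Returns the numeric dataset and a DataFrame
    of the requested categorical columns, aligned on sample id.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=_sep_for(path), index_col=0, dtype=str)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed table {path}: {exc}") from exc
    dup = df.index[df.index.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate sample id(s) in {path}: {sorted(set(dup))}")
    factor_columns = list(factor_columns)
    missing = [c for c in factor_columns if c not in df.columns]
    if missing:
        raise ValueError(f"factor column(s) {missing} not found in {path}")
    factors = df[factor_columns].copy()
    numeric = df.drop(columns=factor_columns)
    values = np.empty(numeric.shape)
    for j, col in enumerate(numeric.columns):
        try:
            values[:, j] = pd.to_numeric(numeric[col], errors="raise")
        except (ValueError, TypeError) as exc:
            raise ValueError(
                f"non-numeric value in column {col!r} of {path} "
                f"(declare it as a factor column?): {exc}"
            ) from exc
    if np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise ValueError(
            f"missing value at sample {numeric.index[i]!r}, variable {numeric.columns[j]!r} in {path}"
        )
    data = Dataset(values, sample_ids=list(numeric.index), var_ids=list(numeric.columns))
    return data, factors


def write_matrix(data: Dataset, path, factors: pd.DataFrame | None = None) -> None:
    """Write a dataset (and optional factor columns) as CSV/TSV."""
    path = Path(path)
    df = pd.DataFrame(data.X, index=data.sample_ids, columns=data.var_ids)
    if factors is not None:
        df = pd.concat([factors.set_axis(df.index), df], axis=1)
    df.index.name = "sample_id"
    df.to_csv(path, sep=_sep_for(path))


# -- model container ----------------------------------------------------


def _schedule_dict(s: TrainingSchedule | None) -> dict | None:
    return None if s is None else s.to_dict()


def save_model(model, path, preprocessor: Preprocessor | None = None) -> None:
    """Serialise a trained model (codebook, supervised map or QC model)
    to a self-describing JSON container."""
    if isinstance(model, SupervisedSOM):
        payload = {
            "kind": "supervised",
            "grid": model.grid.to_dict(),
            "var_ids": list(model.codebook.var_ids),
            "W": model.codebook.W.tolist(),
            "class_planes": model.class_planes.tolist(),
            "class_ids": list(model.class_ids),
            "class_weight": model.class_weight,
            "training_bmus": model.training_bmus.tolist(),
            "training_labels": [str(l) for l in model.training_labels],
            "schedule": _schedule_dict(model.schedule),
        }
    elif isinstance(model, QCModel):
        payload = {
            "kind": "qc",
            "grid": model.grid.to_dict(),
            "var_ids": list(model.codebook.var_ids),
            "W": model.codebook.W.tolist(),
            "statistic": model.statistic,
            "k": model.k,
            "limit": model.limit,
            "percentile": model.percentile,
            "noc_stats": model.noc_stats.tolist(),
            "schedule": _schedule_dict(model.schedule),
        }
    elif isinstance(model, Codebook):
        payload = {
            "kind": "som",
            "grid": model.grid.to_dict(),
            "var_ids": list(model.var_ids),
            "W": model.W.tolist(),
            "schedule": None,
        }
    else:
        raise TypeError(f"cannot serialise object of type {type(model).__name__}")
    container = {
        "format": "somkit-model",
        "format_version": FORMAT_VERSION,
        "toolkit_version": __version__,
        "model": payload,
        "preprocessor": None if preprocessor is None else preprocessor.to_dict(),
    }
    Path(path).write_text(json.dumps(container, sort_keys=True, separators=(",", ":")) + "\n")


def load_model(path):
    """Load a model container; returns ``(model, preprocessor_or_None)``.

    Raises :class:`ModelIntegrityError` on truncated or corrupt files and
    on containers written by a newer major format version.
    """
    try:
        container = json.loads(Path(path).read_text())
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise ModelIntegrityError(f"corrupt or truncated model file {path}: {exc}") from exc
    try:
        if container["format"] != "somkit-model":
            raise ModelIntegrityError(f"{path} is not a somkit model container")
        major = int(str(container["format_version"]).split(".")[0])
        if major > int(FORMAT_VERSION.split(".")[0]):
            raise ModelIntegrityError(
                f"{path} uses format version {container['format_version']}, "
                f"newer than supported {FORMAT_VERSION}"
            )
        payload = container["model"]
        grid = GridSpec.from_dict(payload["grid"])
        W = np.asarray(payload["W"], dtype=float)
        codebook = Codebook(W, grid, var_ids=list(payload["var_ids"]))
        sched = payload.get("schedule")
        schedule = None if sched is None else TrainingSchedule.from_dict(sched)
        kind = payload["kind"]
        if kind == "som":
            model = codebook
        elif kind == "supervised":
            model = SupervisedSOM(
                codebook=codebook,
                class_planes=np.asarray(payload["class_planes"], dtype=float),
                class_ids=list(payload["class_ids"]),
                class_weight=float(payload["class_weight"]),
                training_bmus=np.asarray(payload["training_bmus"], dtype=int),
                training_labels=np.asarray(payload["training_labels"]),
                schedule=schedule,
            )
        elif kind == "qc":
            model = QCModel(
                codebook=codebook,
                statistic=payload["statistic"],
                k=int(payload["k"]),
                limit=float(payload["limit"]),
                percentile=float(payload["percentile"]),
                noc_stats=np.asarray(payload["noc_stats"], dtype=float),
                schedule=schedule,
            )
        else:
            raise ModelIntegrityError(f"unknown model kind {kind!r} in {path}")
        pp = container.get("preprocessor")
        preprocessor = None if pp is None else Preprocessor.from_dict(pp)
    except ModelIntegrityError:
        raise
    except (KeyError, ValueError, TypeError) as exc:
        raise ModelIntegrityError(f"incomplete model container {path}: {exc}") from exc
    return model, preprocessor
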