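"""CSV dataset I/O and columnar draw storage with JSON provenance sidecars."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .growth_mcmc import GrowthPosteriorDraws
from .mixture_mcmc import PosteriorDraws
from .scenarios import LongitudinalDataset, UnivariateDataset

__all__ = [
    "write_univariate_csv",
    "read_univariate_csv",
    "write_longitudinal_csv",
    "read_longitudinal_csv",
    "save_draws",
    "load_draws",
]


def write_univariate_csv(data: UnivariateDataset, path: str | Path, truth: bool = True) -> None:
    """Single-column CSV with header ``y``; truth labels go to a sidecar."""
    path = Path(path)
    data.to_frame().to_csv(path, index=False)
    if truth:
        data.truth_frame().to_csv(path.with_suffix(".labels.csv"), index=False)


def read_univariate_csv(path: str | Path) -> UnivariateDataset:
    path = Path(path)
    frame = pd.read_csv(path)
    if "y" not in frame.columns:
        raise ValueError("expected a column named 'y'")
    sidecar = path.with_suffix(".labels.csv")
    if sidecar.exists():
        labels = pd.read_csv(sidecar)["label"].to_numpy(dtype=int)
    else:
        labels = np.full(len(frame), -1, dtype=int)
    return UnivariateDataset(values=frame["y"].to_numpy(dtype=float), true_labels=labels)


def write_longitudinal_csv(
    data: LongitudinalDataset, path: str | Path, truth: bool = True
) -> None:
    """Long-format CSV ``subject_id,time,y[,covariate...]`` plus truth sidecar."""
    path = Path(path)
    data.frame.to_csv(path, index=False)
    if truth:
        data.truth_frame().to_csv(path.with_suffix(".labels.csv"), index=False)


def read_longitudinal_csv(path: str | Path) -> LongitudinalDataset:
    path = Path(path)
    frame = pd.read_csv(path)
    for col in ("subject_id", "time", "y"):
        if col not in frame.columns:
            raise ValueError(f"expected a column named {col!r}")
    sidecar = path.with_suffix(".labels.csv")
    if sidecar.exists():
        labels = pd.read_csv(sidecar)["label"].to_numpy(dtype=int)
    else:
        labels = np.full(frame["subject_id"].nunique(), -1, dtype=int)
    return LongitudinalDataset(frame=frame, true_labels=labels)


def save_draws(draws, path: str | Path, meta: dict | None = None) -> None:
    """Store a draws container as .npz with a JSON sidecar of configuration."""
    path = Path(path)
    arrays = {
        k: v
        for k, v in vars(draws).items()
        if isinstance(v, np.ndarray) and v is not None
    }
    scalars = {
        k: v for k, v in vars(draws).items() if not isinstance(v, np.ndarray)
    }
    np.savez_compressed(path, **arrays)
    sidecar = {"type": type(draws).__name__, "scalars": scalars, "meta": meta or {}}
    path.with_suffix(".json").write_text(json.dumps(sidecar, default=str, indent=2))


def load_draws(path: str | Path):
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    npz = np.load(path if path.suffix == ".npz" else path.with_suffix(".npz"))
    cls = {"PosteriorDraws": PosteriorDraws, "GrowthPosteriorDraws": GrowthPosteriorDraws}[
        sidecar["type"]
    ]
    fields = {f.name for f in dataclasses.fields(cls)}
    kwargs = {k: npz[k] for k in npz.files if k in fields}
    for k, v in sidecar["scalars"].items():
        if k in fields and k not in kwargs:
            kwargs[k] = int(v) if isinstance(v, str) and v.isdigit() else v
    return cls(**kwargs)
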