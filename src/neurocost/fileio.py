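"""HDF5 / CSV persistence for recordings and response tensors.

Recordings go to HDF5 containers with groups ``/trace`` (data + dt),
``/stimulus_windows`` and ``/truth`` (generating parameters as JSON);
population response tensors go to tidy CSV with columns
``neuron, stimulus, trial, response``.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .decoding import PopulationResponses
from .synth import GroundTruth, SyntheticRecording

__all__ = [
    "write_recording",
    "read_recording",
    "write_population_csv",
    "read_population_csv",
]


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _jsonable(getattr(obj, k)) for k in obj.__dataclass_fields__}
    return obj


def write_recording(path, rec: SyntheticRecording) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("trace")
        g.create_dataset("data", data=rec.trace, compression="gzip")
        g.attrs["dt_ms"] = rec.dt_ms
        g.attrs["units"] = rec.units
        if rec.stimulus_windows:
            starts = np.array([w[0] for w in rec.stimulus_windows])
            stops = np.array([w[1] for w in rec.stimulus_windows])
            labels = np.array([w[2] for w in rec.stimulus_windows], dtype="S64")
            sw = f.create_group("stimulus_windows")
            sw.create_dataset("start_ms", data=starts)
            sw.create_dataset("stop_ms", data=stops)
            sw.create_dataset("label", data=labels)
        t = f.create_group("truth")
        t.attrs["seed"] = rec.truth.seed
        t.attrs["params_json"] = json.dumps(_jsonable(rec.truth.true_params))


def read_recording(path) -> SyntheticRecording:
    with h5py.File(path, "r") as f:
        trace = f["trace/data"][...]
        dt = float(f["trace"].attrs["dt_ms"])
        units = str(f["trace"].attrs.get("units", "mV"))
        windows = []
        if "stimulus_windows" in f:
            sw = f["stimulus_windows"]
            for a, b, lab in zip(sw["start_ms"][...], sw["stop_ms"][...], sw["label"][...]):
                windows.append((float(a), float(b), lab.decode()))
        truth = GroundTruth(
            true_params=json.loads(f["truth"].attrs["params_json"]),
            seed=int(f["truth"].attrs["seed"]),
        )
    return SyntheticRecording(trace, dt, windows, truth, units=units)


def write_population_csv(path, pop: PopulationResponses) -> None:
    n, s, t = pop.responses.shape
    idx = np.indices((n, s, t)).reshape(3, -1)
    df = pd.DataFrame(
        {
            "neuron": idx[0],
            "stimulus": [pop.labels[i] for i in idx[1]],
            "trial": idx[2],
            "response": pop.responses.ravel(),
        }
    )
    df.to_csv(path, index=False)


def read_population_csv(path) -> PopulationResponses:
    df = pd.read_csv(path)
    labels = list(pd.unique(df["stimulus"]))
    n = int(df["neuron"].max()) + 1
    t = int(df["trial"].max()) + 1
    x = np.full((n, len(labels), t), np.nan)
    stim_idx = {lab: i for i, lab in enumerate(labels)}
    x[df["neuron"], df["stimulus"].map(stim_idx), df["trial"]] = df["response"]
    if np.isnan(x).any():
        raise ValueError("incomplete response tensor in CSV")
    return PopulationResponses(x, labels=labels)
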