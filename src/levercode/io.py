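"""Serialization of session bundles (HDF5), trial tables (CSV), configs (YAML).

Bundle layout::

    /behavior/data     (frames, 20) float64
    /behavior/omitted  (frames,) bool
    /activity          (neurons, frames) int8, absent if not simulated/recorded
    /trials/<column>   one dataset per trial-table column
    /meta              attrs: frame_rate, session_id, pursued (bool array)
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .behavior import BehaviorMatrix, CANONICAL_COLUMNS
from .task import SessionBundle, TaskConfig


def save_bundle(bundle: SessionBundle, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        g = f.create_group("behavior")
        g.create_dataset("data", data=bundle.behavior.data)
        g.create_dataset("omitted", data=bundle.behavior.omitted)
        g.attrs["columns"] = list(CANONICAL_COLUMNS)
        if bundle.activity is not None:
            f.create_dataset("activity", data=bundle.activity.astype(np.int8))
        t = f.create_group("trials")
        t.attrs["order"] = list(map(str, bundle.trials.columns))
        for col in bundle.trials.columns:
            v = bundle.trials[col].to_numpy()
            if v.dtype == object:
                v = v.astype("S")
            t.create_dataset(col, data=v)
        m = f.create_group("meta")
        m.attrs["frame_rate"] = bundle.frame_rate
        m.attrs["session_id"] = bundle.session_id
        if bundle.pursued is not None:
            m.attrs["pursued"] = bundle.pursued.astype(bool)


def load_bundle(path: str | Path) -> SessionBundle:
    with h5py.File(path, "r") as f:
        behavior = BehaviorMatrix(
            data=f["behavior/data"][()],
            omitted=f["behavior/omitted"][()].astype(bool),
            frame_rate=float(f["meta"].attrs["frame_rate"]),
        )
        activity = f["activity"][()] if "activity" in f else None
        order = [str(c) for c in f["trials"].attrs.get("order", list(f["trials"]))]
        cols = {}
        for col in order:
            v = f["trials"][col][()]
            if v.dtype.kind == "S":
                v = v.astype(str)
            cols[col] = v
        trials = pd.DataFrame(cols)
        if "init_frame" in trials:
            trials["init_frame"] = trials["init_frame"].astype(int)
        pursued = (
            np.asarray(f["meta"].attrs["pursued"], dtype=bool)
            if "pursued" in f["meta"].attrs
            else None
        )
        return SessionBundle(
            behavior=behavior,
            activity=activity,
            trials=trials,
            frame_rate=behavior.frame_rate,
            session_id=str(f["meta"].attrs["session_id"]),
            pursued=pursued,
        )


def save_trials_csv(bundle: SessionBundle, path: str | Path) -> None:
    bundle.trials.to_csv(path, index=False)


def save_task_config(config: TaskConfig, path: str | Path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(dataclasses.asdict(config), f, sort_keys=True)


def load_task_config(path: str | Path) -> TaskConfig:
    with open(path) as f:
        return TaskConfig(**yaml.safe_load(f))
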