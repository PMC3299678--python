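"""Serialization: traces (CSV / HDF5), state snapshots (JSON / CSV),
biomarker tables, sensitivity matrices and run manifests.

Units on disk follow the figures: ms, mV, mM, A/F; column headers carry them
where they are not implied by the state/current name.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .model import CURRENT_NAMES, STATE_NAMES, SimulationTrace

__all__ = [
    "trace_to_frame", "write_trace_csv", "read_trace_csv",
    "write_trace_hdf5", "read_trace_hdf5",
    "save_state_json", "load_state_json", "save_state_csv", "load_state_csv",
    "write_biomarkers_csv", "write_manifest", "load_snapshot", "SNAPSHOTS",
]

SNAPSHOTS = ("control_1hz", "hf_1hz")

_RECORDED_STATES = ("V", "Cai", "Casl", "Caj", "Ca_sr", "Nai", "Nasl", "Naj",
                    "hL", "d", "f")
_RECORDED_CURRENTS = ("I_NaT", "I_NaL", "I_NCX", "I_NaK", "I_CaL", "I_Kr",
                      "I_K1", "J_rel", "I_stim")


def trace_to_frame(trace: SimulationTrace, states=_RECORDED_STATES,
                   currents=_RECORDED_CURRENTS) -> pd.DataFrame:
    """Tidy wide table: time_ms plus selected state and current columns."""
    cols = {"time_ms": trace.t}
    for name in states:
        cols[name] = trace.state(name)
    for name in currents:
        cols[name] = trace.current(name)
    return pd.DataFrame(cols)


def write_trace_csv(trace: SimulationTrace, path, **kw) -> None:
    trace_to_frame(trace, **kw).to_csv(path, index=False)


def read_trace_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_trace_hdf5(trace: SimulationTrace, path) -> None:
    """Hierarchical container: /time, /states/<name>, /currents/<name>."""
    with h5py.File(path, "w") as f:
        f.create_dataset("time", data=trace.t)
        gs = f.create_group("states")
        for i, name in enumerate(STATE_NAMES):
            gs.create_dataset(name, data=trace.states[:, i])
        gc = f.create_group("currents")
        for i, name in enumerate(CURRENT_NAMES):
            gc.create_dataset(name, data=trace.currents[:, i])
        if trace.final_state is not None:
            f.create_dataset("final_state", data=trace.final_state)


def read_trace_hdf5(path) -> SimulationTrace:
    with h5py.File(path, "r") as f:
        t = f["time"][:]
        states = np.column_stack([f["states"][n][:] for n in STATE_NAMES])
        currents = np.column_stack([f["currents"][n][:] for n in CURRENT_NAMES])
        final = f["final_state"][:] if "final_state" in f else None
    return SimulationTrace(t, states, currents, final)


def save_state_json(state: np.ndarray, path) -> None:
    d = {name: float(state[i]) for i, name in enumerate(STATE_NAMES)}
    Path(path).write_text(json.dumps(d, indent=1))


def load_state_json(path) -> np.ndarray:
    d = json.loads(Path(path).read_text())
    missing = set(STATE_NAMES) - set(d)
    if missing:
        raise ValueError(f"state file missing fields: {sorted(missing)}")
    return np.array([d[name] for name in STATE_NAMES], dtype=float)


def save_state_csv(state: np.ndarray, path) -> None:
    lines = ["name,value"] + [f"{n},{float(state[i])!r}" for i, n in enumerate(STATE_NAMES)]
    Path(path).write_text("\n".join(lines) + "\n")


def load_state_csv(path) -> np.ndarray:
    df = pd.read_csv(path, float_precision="round_trip").set_index("name")["value"]
    return np.array([df[name] for name in STATE_NAMES], dtype=float)


def load_snapshot(name: str) -> np.ndarray:
    """Packaged steady-state snapshot (1-Hz pacing) used as a warm start."""
    if name not in SNAPSHOTS:
        raise KeyError(f"unknown snapshot {name!r}; have {SNAPSHOTS}")
    ref = resources.files("hfcell").joinpath(f"data/{name}.json")
    d = json.loads(ref.read_text())
    return np.array([d[n] for n in STATE_NAMES], dtype=float)


def write_biomarkers_csv(rows, path) -> None:
    """``rows``: iterable of dicts (condition, frequency, beat, biomarkers)."""
    pd.DataFrame(list(rows)).to_csv(path, index=False)


def write_manifest(path, config_echo: dict, **stats) -> None:
    from . import __version__
    manifest = {"config": config_echo, "version": __version__, **stats}
    Path(path).write_text(json.dumps(manifest, indent=1, default=str))
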