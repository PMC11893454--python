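"""On-disk formats: HDF5 for sessions/traces/network snapshots, CSV
fallbacks for sessions, traces, spine maps and ID maps."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .ensemble import SessionEvents
from .roicluster import ROITraces
from .spines import SpineMap

__all__ = [
    "save_session_h5", "load_session_h5",
    "save_session_csv", "load_session_csv",
    "save_traces", "load_traces",
    "save_spine_map_csv", "load_spine_map_csv",
    "save_id_map_csv", "load_id_map_csv",
    "save_network_snapshot",
]


def save_session_h5(path: str | Path, s: SessionEvents) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("events", data=s.events.astype(np.uint8),
                         compression="gzip")
        f["frame_rate"] = s.frame_rate
        if s.centroids is not None:
            f["centroids"] = s.centroids
        if s.footprint_overlap is not None:
            f.create_dataset("footprint_overlap",
                             data=s.footprint_overlap.astype(np.uint8),
                             compression="gzip")
        f.attrs["context_label"] = s.context_label
        f.attrs["session_time"] = s.session_time


def load_session_h5(path: str | Path) -> SessionEvents:
    with h5py.File(path, "r") as f:
        return SessionEvents(
            events=f["events"][()],
            frame_rate=float(f["frame_rate"][()]),
            centroids=f["centroids"][()] if "centroids" in f else None,
            footprint_overlap=(
                f["footprint_overlap"][()].astype(bool)
                if "footprint_overlap" in f else None
            ),
            context_label=str(f.attrs.get("context_label", "")),
            session_time=float(f.attrs.get("session_time", 0.0)),
        )


def save_session_csv(path: str | Path, s: SessionEvents) -> None:
    df = pd.DataFrame(s.events, columns=[f"cell_{i}" for i in s.cell_ids])
    df.insert(0, "frame_rate", s.frame_rate)
    df.to_csv(path, index=False)


def load_session_csv(path: str | Path) -> SessionEvents:
    df = pd.read_csv(path)
    fr = float(df.pop("frame_rate").iloc[0])
    return SessionEvents(events=df.to_numpy(dtype=np.uint8), frame_rate=fr)


def save_traces(path: str | Path, t: ROITraces) -> None:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("traces", data=t.traces, compression="gzip")
            f["frame_rate"] = t.frame_rate
    else:
        df = pd.DataFrame(t.traces, columns=[f"roi_{i}" for i in t.roi_ids])
        df.insert(0, "frame_rate", t.frame_rate)
        df.to_csv(path, index=False)


def load_traces(path: str | Path) -> ROITraces:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            return ROITraces(f["traces"][()], float(f["frame_rate"][()]))
    df = pd.read_csv(path)
    fr = float(df.pop("frame_rate").iloc[0])
    return ROITraces(df.to_numpy(dtype=float), fr)


def save_spine_map_csv(path: str | Path, m: SpineMap) -> None:
    rows = []
    for i in range(len(m.positions)):
        d = int(m.spine_dendrite[i])
        row = {
            "dendrite_id": d,
            "length_um": m.lengths[d],
            "animal": int(m.animals[d]),
            "spine_id": i,
            "position_um": m.positions[i],
        }
        for k, s in enumerate(m.sessions):
            row[f"present_{s}"] = int(m.presence[i, k])
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def load_spine_map_csv(path: str | Path) -> SpineMap:
    df = pd.read_csv(path)
    sessions = [c[len("present_"):] for c in df.columns if c.startswith("present_")]
    dend_ids = sorted(df["dendrite_id"].unique())
    remap = {d: i for i, d in enumerate(dend_ids)}
    lengths = np.empty(len(dend_ids))
    animals = np.zeros(len(dend_ids), int)
    for d, g in df.groupby("dendrite_id"):
        lengths[remap[d]] = g["length_um"].iloc[0]
        if "animal" in g:
            animals[remap[d]] = int(g["animal"].iloc[0])
    presence = df[[f"present_{s}" for s in sessions]].to_numpy(bool)
    return SpineMap(
        lengths=lengths,
        spine_dendrite=df["dendrite_id"].map(remap).to_numpy(int),
        positions=df["position_um"].to_numpy(float),
        presence=presence,
        sessions=sessions,
        animals=animals,
    )


def save_id_map_csv(path: str | Path, id_map: np.ndarray) -> None:
    pd.DataFrame(id_map, columns=["s1", "s2"]).to_csv(path, index=False)


def load_id_map_csv(path: str | Path) -> np.ndarray:
    return pd.read_csv(path).to_numpy(int)


def save_network_snapshot(path: str | Path, net, seed: int | None = None) -> None:
    """HDF5 snapshot of a :class:`~linklab.protocol.LinkingNetwork`."""
    with h5py.File(path, "w") as f:
        g = f.create_group("neurons")
        g["V"] = net.V
        g["I_adapt"] = net.I_adapt
        g["I_inh"] = net.I_inh
        g["ca_soma"] = net.ca_soma
        g["t_exc_soma"] = net.t_exc_soma
        g["layer"] = net.layer
        g = f.create_group("dendrites")
        g["V_d"] = net.V_d
        g["ca_branch"] = net.ca_branch
        g["a_exc"] = net.a_exc
        g["t_exc_dend"] = net.t_exc_dend
        g["owner"] = net.dend_owner
        g = f.create_group("synapses")
        g["dendrite"] = net.syn_dend
        g["source"] = net.syn_src
        g["weight"] = net.syn_w
        g["label"] = net.syn_label
        g["kind"] = net.syn_kind
        g["tag"] = net.syn_tag
        g["potentiated"] = net.syn_pot.astype(np.uint8)
        meta = f.create_group("meta")
        meta.attrs["now_hours"] = net.now_hours
        meta.attrs["params"] = json.dumps(net.p.to_dict())
        if seed is not None:
            meta.attrs["seed"] = seed
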