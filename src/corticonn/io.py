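"""Persistence: HDF5 containers for rasters, currents and LFP, plus plain
text exports (TSV raster, CSV LFP)."""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd

from .lfp import LFPRecord
from .network import CurrentTraces, SpikeRaster

__all__ = [
    "save_run",
    "load_raster",
    "load_currents",
    "save_lfp",
    "load_lfp",
    "raster_to_tsv",
    "lfp_to_csv",
]


def save_run(path, raster: SpikeRaster, currents: CurrentTraces, meta: dict | None = None):
    """Write a simulation run (spikes + current traces) to one HDF5 file."""
    with h5py.File(path, "w") as f:
        g = f.create_group("spikes")
        g.create_dataset("times_ms", data=raster.times)
        g.create_dataset("neuron_ids", data=raster.neuron_ids)
        g.create_dataset("area_of", data=raster.area_of)
        g.create_dataset("is_exc", data=raster.is_exc)
        g.attrs["duration_ms"] = raster.duration
        g.attrs["area_labels"] = json.dumps(raster.area_labels)
        c = f.create_group("currents")
        c.create_dataset("abs_I_E", data=currents.abs_I_E)
        c.create_dataset("abs_I_I", data=currents.abs_I_I)
        c.create_dataset("abs_I_bkg", data=currents.abs_I_bkg)
        c.attrs["dt_ms"] = currents.dt
        c.attrs["n_exc"] = currents.n_exc
        for k, v in (meta or {}).items():
            f.attrs[k] = v


def load_raster(path) -> SpikeRaster:
    with h5py.File(path, "r") as f:
        g = f["spikes"]
        return SpikeRaster(
            g["times_ms"][:],
            g["neuron_ids"][:],
            g["area_of"][:],
            g["is_exc"][:],
            float(g.attrs["duration_ms"]),
            json.loads(g.attrs["area_labels"]),
        )


def load_currents(path) -> CurrentTraces:
    with h5py.File(path, "r") as f:
        c = f["currents"]
        labels = json.loads(f["spikes"].attrs["area_labels"]) if "spikes" in f else []
        return CurrentTraces(
            c["abs_I_E"][:],
            c["abs_I_I"][:],
            c["abs_I_bkg"][:],
            float(c.attrs["dt_ms"]),
            int(c.attrs["n_exc"]),
            labels,
        )


def save_lfp(path, record: LFPRecord):
    with h5py.File(path, "w") as f:
        f.create_dataset("lfp_mv", data=record.signals)
        f.attrs["fs_hz"] = record.fs
        f.attrs["R_mohm"] = record.R_mohm
        f.attrs["transient_cut_s"] = record.transient_cut_s
        f.attrs["area_labels"] = json.dumps(record.area_labels)


def load_lfp(path) -> LFPRecord:
    with h5py.File(path, "r") as f:
        return LFPRecord(
            f["lfp_mv"][:],
            float(f.attrs["fs_hz"]),
            float(f.attrs["R_mohm"]),
            float(f.attrs["transient_cut_s"]),
            json.loads(f.attrs["area_labels"]),
        )


def raster_to_tsv(path, raster: SpikeRaster):
    """Flat TSV export: area, neuron, type, time_ms."""
    ids = raster.neuron_ids
    df = pd.DataFrame(
        {
            "area": raster.area_of[ids],
            "neuron": ids,
            "type": np.where(raster.is_exc[ids], "E", "I"),
            "time_ms": raster.times,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def lfp_to_csv(path, record: LFPRecord):
    t = np.arange(record.signals.shape[0]) / record.fs
    labels = record.area_labels or [f"A{i}" for i in range(record.n_areas)]
    df = pd.DataFrame(record.signals, columns=labels)
    df.insert(0, "time_s", t)
    df.to_csv(path, index=False)
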