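"""File containers: trajectory CSV, density-grid HDF5, JSON reports.

All writes are atomic (temp file + rename) and every artifact gets a
sidecar manifest echoing the fully resolved configuration, so any run can
be reproduced bit-identically from its outputs alone.
"""

from __future__ import annotations

import json
import os
import tempfile
from typing import Optional

import h5py
import numpy as np

from .simulate import DensityGrid, EnsembleTrajectory

__all__ = [
    "atomic_write_bytes",
    "write_json",
    "write_manifest",
    "save_trajectory_csv",
    "save_density_h5",
    "load_density_h5",
]


def _atomic(path: str, writer):
    d = os.path.dirname(os.path.abspath(path)) or "."
    os.makedirs(d, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=d, suffix=".tmp")
    os.close(fd)
    try:
        writer(tmp)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def atomic_write_bytes(path: str, data: bytes):
    _atomic(path, lambda tmp: open(tmp, "wb").write(data))


def write_json(path: str, obj):
    atomic_write_bytes(
        path, (json.dumps(obj, indent=2, default=_json_default) + "\n").encode())


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def write_manifest(artifact_path: str, config: dict):
    from . import __version__

    write_json(artifact_path + ".manifest.json",
               {"config": config, "version": __version__})


def save_trajectory_csv(path: str, traj: EnsembleTrajectory):
    """CSV with header t, w, x1..xn; full round-trip-safe float precision."""
    n = traj.dim
    header = "t,w," + ",".join(f"x{i+1}" for i in range(n))

    def writer(tmp):
        with open(tmp, "w") as fh:
            fh.write(header + "\n")
            for w in range(traj.walkers):
                for k, t in enumerate(traj.times):
                    coords = ",".join(repr(float(v)) for v in traj.states[w, k])
                    fh.write(f"{t!r},{w},{coords}\n")

    _atomic(path, writer)


def save_density_h5(path: str, grid: DensityGrid):
    def writer(tmp):
        with h5py.File(tmp, "w") as f:
            for i, e in enumerate(grid.edges):
                f.create_dataset(f"edges_{i}", data=np.asarray(e))
            f.create_dataset("masses", data=grid.masses)
            f.create_dataset("counts", data=grid.counts)
            f.create_dataset("mask", data=grid.mask.astype(np.uint8))
            if grid.h is not None:
                f.create_dataset("h", data=grid.h)
            f.attrs["n_samples"] = grid.n_samples
            f.attrs["out_of_box"] = grid.out_of_box
            f.attrs["metadata"] = json.dumps(grid.metadata, default=_json_default)

    _atomic(path, writer)


def load_density_h5(path: str) -> DensityGrid:
    with h5py.File(path, "r") as f:
        ndim = len([k for k in f.keys() if k.startswith("edges_")])
        edges = [np.asarray(f[f"edges_{i}"]) for i in range(ndim)]
        grid = DensityGrid(
            edges=edges,
            masses=np.asarray(f["masses"]),
            counts=np.asarray(f["counts"]),
            mask=np.asarray(f["mask"]).astype(bool),
            n_samples=int(f.attrs["n_samples"]),
            out_of_box=int(f.attrs["out_of_box"]),
            metadata=json.loads(f.attrs["metadata"]),
            h=np.asarray(f["h"]) if "h" in f else None,
        )
    return grid
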