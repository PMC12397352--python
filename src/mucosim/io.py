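"""File writers/readers: CSV time-series, HDF5 and legacy-VTK snapshots.

Snapshots are self-describing: grid dimensions, spacing, layer interface,
time stamp and SI units travel with the fields.  The VTK writer emits
legacy ASCII ``STRUCTURED_POINTS`` datasets readable by standard viewers.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .grid import GridSpec

__all__ = ["write_timeseries", "write_snapshot_hdf5", "read_snapshot_hdf5",
           "write_snapshot_vtk", "write_markers_csv"]


def write_timeseries(df: pd.DataFrame, path) -> Path:
    """Write a metrics time-series as CSV (deterministic column order)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def write_snapshot_hdf5(fields: dict, grid: GridSpec, t: float, path) -> Path:
    """Write named fields (cell- or face-shaped arrays) plus grid metadata."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as fh:
        fh.attrs["time_s"] = t
        fh.attrs["dx_m"] = grid.dx
        fh.attrs["lz_m"] = grid.lz
        fh.attrs["z_interface_m"] = grid.z_interface
        fh.attrs["shape"] = grid.shape
        fh.attrs["units"] = "SI"
        for name, arr in fields.items():
            fh.create_dataset(name, data=np.asarray(arr))
    return path


def read_snapshot_hdf5(path):
    """Read a snapshot back as ``(fields, attrs)`` dictionaries."""
    with h5py.File(path, "r") as fh:
        fields = {k: fh[k][...] for k in fh.keys()}
        attrs = dict(fh.attrs)
    return fields, attrs


def write_snapshot_vtk(fields: dict, grid: GridSpec, t: float, path) -> Path:
    """Write cell-centred fields as a legacy ASCII VTK structured-points file.

    Scalars are written as ``SCALARS``; 3-tuples of arrays as ``VECTORS``.
    Arrays must have the cell-centre shape ``grid.shape``.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nx, ny, nz = grid.shape
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"mucosim snapshot t={t:.9e} s\n")
        fh.write("ASCII\nDATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        fh.write(f"ORIGIN {grid.dx / 2:.9e} {grid.dx / 2:.9e} {grid.dx / 2:.9e}\n")
        fh.write(f"SPACING {grid.dx:.9e} {grid.dx:.9e} {grid.dx:.9e}\n")
        fh.write(f"POINT_DATA {nx * ny * nz}\n")
        for name, arr in fields.items():
            if isinstance(arr, (tuple, list)):
                comps = [np.asarray(a) for a in arr]
                fh.write(f"VECTORS {name} double\n")
                flat = np.stack([c.transpose(2, 1, 0).ravel() for c in comps],
                                axis=1)
                np.savetxt(fh, flat, fmt="%.9e")
            else:
                a = np.asarray(arr)
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                np.savetxt(fh, a.transpose(2, 1, 0).ravel(), fmt="%.9e")
    return path


def write_markers_csv(markers, path) -> Path:
    """Columnar marker export: cilium id, marker index, X, U, dV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    n = len(markers)
    cid = (markers.cilium_id if markers.cilium_id is not None
           else np.zeros(n, dtype=int))
    df = pd.DataFrame({
        "cilium": cid, "marker": np.arange(n),
        "x_m": markers.X[:, 0], "y_m": markers.X[:, 1], "z_m": markers.X[:, 2],
        "ux_m_s": markers.U[:, 0], "uy_m_s": markers.U[:, 1],
        "uz_m_s": markers.U[:, 2], "dV_m3": markers.dV,
    })
    df.to_csv(path, index=False)
    return path
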