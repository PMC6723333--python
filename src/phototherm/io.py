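"""Cube and tabular output formats.

Voxel cubes are written as raw little-endian float64 in x-fastest
(Fortran) order next to a JSON sidecar carrying the shape, voxel size,
units and run provenance — a deliberately language-neutral format.
A legacy-ASCII VTK structured-points writer is provided for quick
visualisation, and small tables go to CSV.
"""

from __future__ import annotations

import csv
import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .geometry import VoxelGrid

__all__ = ["write_cube", "read_cube", "write_vtk", "write_csv", "sha256_file"]


def write_cube(
    path: str | Path,
    array: np.ndarray,
    grid: VoxelGrid,
    units: str,
    meta: Mapping | None = None,
) -> Path:
    """Write a voxel cube as ``<path>.raw`` + ``<path>.json`` sidecar."""
    path = Path(path)
    raw = path.with_suffix(".raw")
    arr = np.asarray(array, dtype="<f8")
    arr.flatten(order="F").tofile(raw)
    sidecar = {
        "shape": list(arr.shape),
        "dtype": "<f8",
        "order": "x-fastest",
        "voxel_size_mm": [float(e) for e in grid.edges],
        "bounds_mm": [list(map(float, grid.bounds[0])),
                      list(map(float, grid.bounds[1]))],
        "units": units,
    }
    if meta:
        sidecar.update(meta)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return raw


def read_cube(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read a cube written by :func:`write_cube`; returns (array, sidecar)."""
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    arr = np.fromfile(path.with_suffix(".raw"), dtype=sidecar["dtype"])
    arr = arr.reshape(sidecar["shape"], order="F")
    return arr, sidecar


def write_vtk(path: str | Path, array: np.ndarray, grid: VoxelGrid,
              name: str = "value") -> Path:
    """Legacy-ASCII VTK structured-points export of a voxel cube."""
    path = Path(path)
    arr = np.asarray(array, dtype=float)
    nx, ny, nz = arr.shape
    e = grid.edges
    lo = grid.lo + 0.5 * e
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"{name}\nASCII\nDATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        fh.write(f"ORIGIN {lo[0]} {lo[1]} {lo[2]}\n")
        fh.write(f"SPACING {e[0]} {e[1]} {e[2]}\n")
        fh.write(f"POINT_DATA {nx * ny * nz}\n")
        fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
        np.savetxt(fh, arr.flatten(order="F"), fmt="%.8g")
    return path


def write_csv(path: str | Path, header: Sequence[str],
              rows: Iterable[Sequence]) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        writer.writerows(rows)
    return path


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
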