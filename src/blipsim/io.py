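"""Shared file I/O: contour CSV, grid NPZ, legacy VTK, Wavefront OBJ, metadata.

Conventions: coordinates in micrometres (phase-field grids are dimensionless
box units, recorded in their metadata); contour CSV has a header ``x,y`` and
one vertex per row, implicitly closed (last connects back to first); NPZ
archives store named arrays plus box metadata; VTK output is legacy
structured-points ASCII readable by standard viewers.
"""

from __future__ import annotations

import json
import platform
import time
from pathlib import Path

import numpy as np

from .surface_math import Contour2D

__all__ = [
    "read_contour_csv",
    "write_contour_csv",
    "write_radii_csv",
    "write_grid_npz",
    "read_grid_npz",
    "write_vtk",
    "write_mesh_obj",
    "packed_cell_to_json",
    "packed_cell_from_json",
    "run_metadata",
]


def write_contour_csv(contour: Contour2D | np.ndarray, path) -> None:
    v = contour.vertices if isinstance(contour, Contour2D) else np.asarray(contour)
    with open(path, "w") as fh:
        fh.write("x,y\n")
        for x, y in v:
            fh.write(f"{float(x)!r},{float(y)!r}\n")


def read_contour_csv(path) -> Contour2D:
    rows = []
    with open(path) as fh:
        header = fh.readline().strip()
        if header.replace(" ", "") != "x,y":
            raise ValueError(f"{path}: expected header 'x,y', got {header!r}")
        for ln, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise ValueError(f"{path}:{ln}: expected two columns")
            try:
                rows.append((float(parts[0]), float(parts[1])))
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: {exc}") from None
    return Contour2D(np.asarray(rows))


def write_radii_csv(radii: np.ndarray, path) -> None:
    with open(path, "w") as fh:
        fh.write("blip_id,radius_um\n")
        for k, r in enumerate(np.asarray(radii).ravel()):
            fh.write(f"{k},{float(r)!r}\n")


def write_grid_npz(path, box=None, **arrays) -> None:
    """NPZ archive of named arrays with optional box metadata (bit-exact)."""
    meta = {} if box is None else {"box": np.asarray(box)}
    np.savez(path, **arrays, **meta)


def read_grid_npz(path) -> dict:
    with np.load(path) as z:
        return {k: z[k] for k in z.files}


def write_vtk(grid_array: np.ndarray, path, name: str = "field",
              spacing: float = 1.0, origin=(0.0, 0.0, 0.0)) -> None:
    """Legacy-VTK structured points (ASCII) for a 2D or 3D scalar grid."""
    a = np.asarray(grid_array)
    dims = list(a.shape) + [1] * (3 - a.ndim)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"{name}\nASCII\nDATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {dims[0]} {dims[1]} {dims[2]}\n")
        fh.write(f"ORIGIN {origin[0]} {origin[1]} {origin[2]}\n")
        fh.write(f"SPACING {spacing} {spacing} {spacing}\n")
        fh.write(f"POINT_DATA {a.size}\n")
        fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
        flat = a.reshape(-1, order="F")
        for start in range(0, flat.size, 9):
            fh.write(" ".join(f"{v:.6g}" for v in flat[start:start + 9]) + "\n")


def write_mesh_obj(vertices: np.ndarray, faces: np.ndarray, path) -> None:
    """Wavefront OBJ (1-based face indices)."""
    with open(path, "w") as fh:
        for v in np.asarray(vertices):
            fh.write(f"v {float(v[0])!r} {float(v[1])!r} {float(v[2])!r}\n")
        for f in np.asarray(faces, dtype=int):
            fh.write("f " + " ".join(str(i + 1) for i in f) + "\n")


def packed_cell_to_json(cell, path=None):
    from .blip_packing import PackedCell  # noqa: F401 (type reference)

    doc = {
        "base_radius": cell.base_radius,
        "centers": cell.centers.tolist(),
        "radii": cell.radii.tolist(),
        "frozen": cell.frozen.astype(bool).tolist(),
    }
    if path is not None:
        Path(path).write_text(json.dumps(doc))
    return doc


def packed_cell_from_json(source):
    from .blip_packing import PackedCell

    doc = json.loads(Path(source).read_text()) if not isinstance(source, dict) \
        else source
    return PackedCell(doc["base_radius"], np.asarray(doc["centers"]),
                      np.asarray(doc["radii"]), np.asarray(doc["frozen"]))


def run_metadata(params: dict, seed: int | None = None, **extra) -> dict:
    """Reproducibility block written next to every artifact set."""
    meta = {
        "params": params,
        "seed": seed,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "python": platform.python_version(),
        "numpy": np.__version__,
    }
    meta.update(extra)
    return meta
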