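"""Field export: legacy-ASCII VTK polydata and flat CSV tables."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import SphericalMesh

__all__ = ["write_mesh_vtk", "write_mesh_csv", "write_track_csv"]


def write_mesh_vtk(path, mesh: SphericalMesh, fields: dict[str, np.ndarray] | None = None) -> None:
    """Write the mesh nodes and per-node scalar fields as VTK polydata
    (legacy ASCII), viewable in ParaView/VisIt."""
    fields = fields or {}
    points = mesh.directions * mesh.worn_radius[:, None]
    n = mesh.n_nodes
    lines = [
        "# vtk DataFile Version 3.0",
        "polywear cup bearing surface",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {n} double",
    ]
    lines += [f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}" for p in points]
    lines.append(f"VERTICES {n} {2 * n}")
    lines += [f"1 {i}" for i in range(n)]
    lines.append(f"POINT_DATA {n}")
    for name, values in {"area": mesh.area, "penetration": mesh.penetration, **fields}.items():
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        lines += [f"{v:.9g}" for v in np.asarray(values, dtype=float)]
    Path(path).write_text("\n".join(lines) + "\n")


def write_mesh_csv(path, mesh: SphericalMesh, fields: dict[str, np.ndarray] | None = None) -> None:
    """Flat per-node table: polar angle, azimuth, area plus scalar fields."""
    data = {
        "polar_rad": mesh.polar_angle,
        "azimuth_rad": mesh.azimuth,
        "area_mm2": mesh.area,
        "penetration_mm": mesh.penetration,
    }
    for name, values in (fields or {}).items():
        data[name] = np.asarray(values, dtype=float)
    pd.DataFrame(data).to_csv(path, index=False)


def write_track_csv(path, tracks: dict[int, np.ndarray]) -> None:
    """Slide-track polylines, one block of rows per node index."""
    frames = []
    for node, pts in tracks.items():
        frames.append(
            pd.DataFrame(
                {
                    "node": node,
                    "x_mm": pts[:, 0],
                    "y_mm": pts[:, 1],
                    "z_mm": pts[:, 2] if pts.shape[1] > 2 else np.nan,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
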