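"""Legacy-VTK ASCII export of meridional meshes and fields for inspection."""

from __future__ import annotations

import numpy as np


def write_vtk_mesh(path, points: np.ndarray, triangles: np.ndarray, point_data: dict | None = None) -> None:
    """Write a 2-D triangulation (z-coordinate 0) as a legacy VTK file.

    ``point_data`` maps field names to per-vertex scalar arrays.
    """
    points = np.asarray(points, float)
    triangles = np.asarray(triangles)
    n, m = points.shape[0], triangles.shape[0]
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nmeridional mesh\nASCII\nDATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {n} double\n")
        for x, y in points:
            fh.write(f"{x:.10g} {y:.10g} 0\n")
        fh.write(f"CELLS {m} {4 * m}\n")
        for t in triangles:
            fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")
        fh.write(f"CELL_TYPES {m}\n")
        fh.write("5\n" * m)
        if point_data:
            fh.write(f"POINT_DATA {n}\n")
            for name, vals in point_data.items():
                vals = np.asarray(vals, float)
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                fh.write("\n".join(f"{v:.10g}" for v in vals) + "\n")
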