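"""Output writers: legacy ASCII VTK fields, CSV profiles, JSON summaries."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .mesh import Mesh

__all__ = ["write_vtk", "write_json"]

_VTK_CELL = {1: 5, 2: 22}  # triangle, quadratic triangle


def write_vtk(mesh: Mesh, path, point_data=None, cell_data=None) -> None:
    """Write the mesh and nodal/cell fields as a legacy ASCII VTK file.

    Quadratic triangles use the VTK_QUADRATIC_TRIANGLE node ordering
    (corners, then mid-edge nodes m01, m12, m20), which matches the
    internal element layout.  The element region tags are always written
    as cell data ``region``.
    """
    path = Path(path)
    nn = mesh.elements.shape[1]
    lines = [
        "# vtk DataFile Version 3.0",
        "tumorflow mesh",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {mesh.n_nodes} double",
    ]
    for x, y in mesh.nodes:
        lines.append(f"{x:.10g} {y:.10g} 0")
    lines.append(f"CELLS {mesh.n_elements} {mesh.n_elements * (nn + 1)}")
    for el in mesh.elements:
        lines.append(f"{nn} " + " ".join(map(str, el)))
    lines.append(f"CELL_TYPES {mesh.n_elements}")
    lines.extend([str(_VTK_CELL[mesh.order])] * mesh.n_elements)

    cell_data = {"region": mesh.region_tag, **(cell_data or {})}
    lines.append(f"CELL_DATA {mesh.n_elements}")
    for name, arr in cell_data.items():
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        lines.extend(f"{v:.10g}" for v in np.asarray(arr, dtype=float))
    if point_data:
        lines.append(f"POINT_DATA {mesh.n_nodes}")
        for name, arr in point_data.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim == 1:
                lines.append(f"SCALARS {name} double 1")
                lines.append("LOOKUP_TABLE default")
                lines.extend(f"{v:.10g}" for v in arr)
            else:
                lines.append(f"VECTORS {name} double")
                lines.extend(f"{v[0]:.10g} {v[1]:.10g} 0" for v in arr)
    path.write_text("\n".join(lines) + "\n")


def write_json(obj, path) -> None:
    """JSON dump with numpy scalars/arrays coerced to plain Python."""

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")
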