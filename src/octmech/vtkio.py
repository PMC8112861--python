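"""Minimal legacy-VTK (ASCII unstructured grid) export of stress fields.

Writes quadratic-triangle meshes (VTK cell type 22) with nodal
displacement as point data and region label / stress components /
von Mises as cell data, for inspection in ParaView-style viewers.
"""

from __future__ import annotations

from pathlib import Path

from .fea import Mesh, StressField

__all__ = ["write_vtk"]


def write_vtk(path, mesh: Mesh, field: StressField | None = None,
              title: str = "octmech stress field") -> Path:
    path = Path(path)
    lines = ["# vtk DataFile Version 3.0", title, "ASCII",
             "DATASET UNSTRUCTURED_GRID",
             f"POINTS {mesh.n_nodes} double"]
    for x, y in mesh.nodes:
        lines.append(f"{x:.9g} {y:.9g} 0")
    m = mesh.n_elements
    lines.append(f"CELLS {m} {7 * m}")
    for el in mesh.elements:
        lines.append("6 " + " ".join(str(int(v)) for v in el))
    lines.append(f"CELL_TYPES {m}")
    lines.extend(["22"] * m)

    lines.append(f"CELL_DATA {m}")
    lines.append("SCALARS region int 1")
    lines.append("LOOKUP_TABLE default")
    lines.extend(str(int(r)) for r in mesh.region_id)
    if field is not None:
        for name, vals in (("von_mises_kpa", field.vm),
                           ("sxx_kpa", field.sxx), ("syy_kpa", field.syy),
                           ("txy_kpa", field.txy), ("szz_kpa", field.szz)):
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            lines.extend(f"{v:.9g}" for v in vals)
        lines.append(f"POINT_DATA {mesh.n_nodes}")
        lines.append("VECTORS displacement_mm double")
        for ux, uy in field.displacement:
            lines.append(f"{ux:.9g} {uy:.9g} 0")
    path.write_text("\n".join(lines) + "\n")
    return path
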