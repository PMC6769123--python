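"""Minimal ASCII VTU (VTK XML unstructured grid) writer.

Covers exactly what the solver exports: hex8/tet4 meshes with scalar or
3-vector point data and scalar cell data.  Output is plain text and can be
opened directly in ParaView.
"""

from __future__ import annotations

import numpy as np

_VTK_TYPE = {"tet4": 10, "hex8": 12}

__all__ = ["write_vtu"]


def _fmt(a: np.ndarray) -> str:
    return " ".join(f"{x:.9g}" for x in np.asarray(a).ravel())


def write_vtu(path, mesh, point_data=None, cell_data=None) -> None:
    """Write a mesh plus nodal/element fields to an XML .vtu file."""
    point_data = point_data or {}
    cell_data = cell_data or {}
    n_pts, n_cells = mesh.n_nodes, mesh.n_cells
    nen = mesh.cells.shape[1]
    vtk_type = _VTK_TYPE[mesh.cell_type]

    parts = []
    w = parts.append
    w('<?xml version="1.0"?>')
    w('<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">')
    w("<UnstructuredGrid>")
    w(f'<Piece NumberOfPoints="{n_pts}" NumberOfCells="{n_cells}">')
    w("<Points>")
    w('<DataArray type="Float64" NumberOfComponents="3" format="ascii">')
    w(_fmt(mesh.points))
    w("</DataArray></Points>")
    w("<Cells>")
    w('<DataArray type="Int64" Name="connectivity" format="ascii">')
    w(" ".join(str(i) for i in mesh.cells.ravel()))
    w("</DataArray>")
    w('<DataArray type="Int64" Name="offsets" format="ascii">')
    w(" ".join(str(nen * (i + 1)) for i in range(n_cells)))
    w("</DataArray>")
    w('<DataArray type="UInt8" Name="types" format="ascii">')
    w(" ".join(str(vtk_type) for _ in range(n_cells)))
    w("</DataArray></Cells>")

    w("<PointData>")
    for name, arr in point_data.items():
        arr = np.asarray(arr)
        ncomp = 1 if arr.ndim == 1 else arr.shape[1]
        w(f'<DataArray type="Float64" Name="{name}" '
          f'NumberOfComponents="{ncomp}" format="ascii">')
        w(_fmt(arr))
        w("</DataArray>")
    w("</PointData>")
    w("<CellData>")
    for name, arr in cell_data.items():
        w(f'<DataArray type="Float64" Name="{name}" '
          f'NumberOfComponents="1" format="ascii">')
        w(_fmt(arr))
        w("</DataArray>")
    w("</CellData>")
    w("</Piece></UnstructuredGrid></VTKFile>")
    with open(path, "w") as fh:
        fh.write("\n".join(parts))
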