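"""File I/O: VTU (VTK XML unstructured grid) export/import, STL surface
export, geometry JSON, and tidy report tables.

The VTU writer emits plain ASCII appended-free XML readable by ParaView and
other VTK-based tools; string cell labels (part, region, zone) are encoded
as integer arrays whose legend is embedded in the FieldData block.
"""

from __future__ import annotations

import dataclasses
import json
import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np
import pandas as pd

from .meshing import FEMesh, boundary_faces


def _fmt(arr: np.ndarray) -> str:
    flat = np.asarray(arr).reshape(-1)
    if flat.dtype.kind in "iu":
        return " ".join(str(int(v)) for v in flat)
    return " ".join(f"{v:.9g}" for v in flat)


def _encode_labels(values: np.ndarray) -> tuple[np.ndarray, list]:
    levels = sorted(set(values.tolist()))
    lookup = {v: i for i, v in enumerate(levels)}
    return np.array([lookup[v] for v in values], dtype=int), levels


def write_vtu(mesh: FEMesh, path, point_data: dict | None = None,
              cell_data: dict | None = None) -> None:
    """Write the mesh (+ optional fields) as an ASCII .vtu file.

    point_data arrays are (N,) or (N, k); cell_data arrays (M,) or (M, k).
    The part/region/zone labels and fiber directions are always included.
    """
    path = Path(path)
    point_data = dict(point_data or {})
    cell_data = dict(cell_data or {})
    legends = {}
    for name, values in (("part", mesh.part), ("region", mesh.region),
                         ("zone", mesh.zone)):
        codes, levels = _encode_labels(values)
        cell_data[name] = codes
        legends[name] = levels
    cell_data.setdefault("fiber_dir", mesh.fiber_dir)

    root = ET.Element("VTKFile", type="UnstructuredGrid", version="0.1",
                      byte_order="LittleEndian")
    grid = ET.SubElement(root, "UnstructuredGrid")
    piece = ET.SubElement(grid, "Piece", NumberOfPoints=str(mesh.n_nodes),
                          NumberOfCells=str(mesh.n_elements))

    fd = ET.SubElement(grid, "FieldData")
    legend_text = json.dumps(legends)
    arr = ET.SubElement(fd, "DataArray", type="Int8", Name="label_legend_json",
                        NumberOfTuples=str(len(legend_text)), format="ascii")
    arr.text = " ".join(str(b) for b in legend_text.encode())

    pts = ET.SubElement(piece, "Points")
    arr = ET.SubElement(pts, "DataArray", type="Float64", Name="Points",
                        NumberOfComponents="3", format="ascii")
    arr.text = _fmt(mesh.nodes)

    cells = ET.SubElement(piece, "Cells")
    conn = ET.SubElement(cells, "DataArray", type="Int64", Name="connectivity",
                         format="ascii")
    conn.text = _fmt(mesh.tets)
    offs = ET.SubElement(cells, "DataArray", type="Int64", Name="offsets",
                         format="ascii")
    offs.text = _fmt(4 * (np.arange(mesh.n_elements) + 1))
    types = ET.SubElement(cells, "DataArray", type="UInt8", Name="types",
                          format="ascii")
    types.text = _fmt(np.full(mesh.n_elements, 10))  # VTK_TETRA

    def add_fields(parent_name: str, data: dict, n_expect: int):
        parent = ET.SubElement(piece, parent_name)
        for name, values in data.items():
            values = np.asarray(values)
            if len(values) != n_expect:
                raise ValueError(f"field {name!r}: length {len(values)} != {n_expect}")
            ncomp = 1 if values.ndim == 1 else values.shape[1]
            dtype = "Int64" if values.dtype.kind in "iu" else "Float64"
            a = ET.SubElement(parent, "DataArray", type=dtype, Name=name,
                              NumberOfComponents=str(ncomp), format="ascii")
            a.text = _fmt(values)

    add_fields("PointData", point_data, mesh.n_nodes)
    add_fields("CellData", cell_data, mesh.n_elements)

    ET.indent(root)
    path.write_text(ET.tostring(root, encoding="unicode"))


def read_vtu(path) -> tuple[np.ndarray, np.ndarray, dict, dict]:
    """Read an ASCII .vtu written by :func:`write_vtu`.

    Returns (nodes, tets, point_data, cell_data); label arrays come back as
    the encoded integer codes.
    """
    root = ET.parse(Path(path)).getroot()
    piece = root.find(".//Piece")
    pts = piece.find("Points/DataArray")
    nodes = np.fromstring(pts.text, sep=" ").reshape(-1, 3)
    conn = piece.find("Cells/DataArray[@Name='connectivity']")
    tets = np.fromstring(conn.text, sep=" ", dtype=int).reshape(-1, 4)

    def grab(tag):
        out = {}
        el = piece.find(tag)
        if el is None:
            return out
        for arr in el.findall("DataArray"):
            dtype = int if arr.get("type", "").startswith("Int") else float
            vals = np.fromstring(arr.text, sep=" ", dtype=dtype)
            ncomp = int(arr.get("NumberOfComponents", "1"))
            out[arr.get("Name")] = vals.reshape(-1, ncomp) if ncomp > 1 else vals
        return out

    return nodes, tets, grab("PointData"), grab("CellData")


def solution_to_vtu(model, solution, path) -> None:
    """Export a solved state: displacements (point), stress and principal
    stresses (cell), contact pressure (point)."""
    from .materials import principal_stresses

    pcs = principal_stresses(solution.stress)
    pressure = np.zeros(model.mesh.n_nodes)
    for state in solution.contact.values():
        if state is None or state.fn is None or not len(state.active):
            continue
        ids = state.pair.slave_nodes[state.active]
        areas = state.pair.slave_areas[state.active]
        pressure[ids] = np.maximum(pressure[ids], state.fn / np.maximum(areas, 1e-12))
    write_vtu(model.mesh, path,
              point_data={"displacement": solution.u,
                          "contact_pressure": pressure},
              cell_data={"stress_voigt": solution.stress,
                         "max_pcs": pcs[:, 0], "min_pcs": pcs[:, 2]})


def write_surface_stl(mesh: FEMesh, path) -> None:
    """Export the mesh boundary as a triangulated STL surface."""
    import trimesh

    tri, _ = boundary_faces(mesh)
    surface = trimesh.Trimesh(vertices=mesh.nodes, faces=tri, process=False)
    surface.export(str(path))


def geometry_to_json(geometry, path=None) -> dict:
    """Serialize the analytic geometry description (parameters, landmark and
    attachment points) to the package's JSON geometry schema."""
    params = dataclasses.asdict(geometry.params)
    doc = {
        "schema": "meniscusfe-geometry/1",
        "params": params,
        "condyle_center_z": geometry.condyle_center_z,
        "landmarks": {k: np.asarray(v).tolist() for k, v in geometry.landmarks.items()},
        "ligament_attachments": {
            k: {"horn": np.asarray(h).tolist(), "insertion": np.asarray(i).tolist()}
            for k, (h, i) in geometry.ligament_attachments.items()},
    }
    if path is not None:
        Path(path).write_text(json.dumps(doc, indent=2))
    return doc


def convergence_trace_csv(solution, path) -> None:
    df = pd.DataFrame(solution.trace, columns=["load_factor", "iteration", "residual"])
    df.to_csv(path, index=False)


def reports_to_csv(reports: list, path) -> pd.DataFrame:
    """Tidy CSV of a list of report dataclasses."""
    rows = []
    for rep in reports:
        row = dataclasses.asdict(rep)
        rows.append({k: (v.tolist() if isinstance(v, np.ndarray) else v)
                     for k, v in row.items()})
    df = pd.DataFrame(rows)
    if path is not None:
        df.to_csv(path, index=False)
    return df
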