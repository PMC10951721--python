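"""Mesh serialization: ASCII VTU (XML unstructured grid) and STL export.

VTU is the primary format: it carries the hexahedral connectivity, a
``region`` cell-data array, and a JSON metadata block (region names,
facet sets, caps, tie constraints) embedded as a UInt8 field-data array
so a written mesh round-trips losslessly through :func:`read_mesh`.
Generic VTK viewers read the geometry and the region array and ignore
the metadata block.

STL is a surface-only export convenience (triangulated outer+inner
surfaces); it cannot be read back as a :class:`~vesselmech.meshing.WallMesh`.
"""

from __future__ import annotations

import json
from pathlib import Path
from xml.etree import ElementTree as ET

import numpy as np

from .meshing import Cap, Ties, WallMesh

SUPPORTED_WRITE = (".vtu", ".stl")
SUPPORTED_READ = (".vtu",)

VTK_HEXAHEDRON = 12


class MeshIOError(ValueError):
    """Unsupported format or malformed mesh file."""


def write_mesh(mesh: WallMesh, path: str | Path,
               point_data: dict[str, np.ndarray] | None = None,
               cell_data: dict[str, np.ndarray] | None = None) -> Path:
    """Write ``mesh`` (plus optional result fields) to ``path``.

    The extension selects the format; unknown extensions raise
    :class:`MeshIOError` listing the supported ones.
    """
    path = Path(path)
    ext = path.suffix.lower()
    if ext == ".vtu":
        _write_vtu(mesh, path, point_data or {}, cell_data or {})
    elif ext == ".stl":
        _write_stl(mesh, path)
    else:
        raise MeshIOError(
            f"unsupported mesh format {ext!r}; supported for writing: "
            f"{', '.join(SUPPORTED_WRITE)}")
    return path


def read_mesh(path: str | Path) -> WallMesh:
    """Read a VTU file written by :func:`write_mesh` back into a WallMesh."""
    path = Path(path)
    ext = path.suffix.lower()
    if ext not in SUPPORTED_READ:
        raise MeshIOError(
            f"unsupported mesh format {ext!r}; supported for reading: "
            f"{', '.join(SUPPORTED_READ)}")
    return _read_vtu(path)


# ---------------------------------------------------------------------------
# VTU
# ---------------------------------------------------------------------------

def _fmt_array(a: np.ndarray) -> str:
    a = np.asarray(a)
    if a.dtype.kind == "f":
        return " ".join(repr(float(x)) for x in a.ravel())
    return " ".join(str(int(x)) for x in a.ravel())


def _data_array(parent: ET.Element, name: str, a: np.ndarray,
                vtk_type: str, ncomp: int | None = None) -> None:
    el = ET.SubElement(parent, "DataArray", {
        "type": vtk_type, "Name": name, "format": "ascii"})
    if ncomp is not None:
        el.set("NumberOfComponents", str(ncomp))
    el.text = _fmt_array(a)


def _write_vtu(mesh: WallMesh, path: Path,
               point_data: dict[str, np.ndarray],
               cell_data: dict[str, np.ndarray]) -> None:
    root = ET.Element("VTKFile", {"type": "UnstructuredGrid",
                                  "version": "0.1", "byte_order": "LittleEndian"})
    ug = ET.SubElement(root, "UnstructuredGrid")
    piece = ET.SubElement(ug, "Piece", {
        "NumberOfPoints": str(mesh.n_nodes), "NumberOfCells": str(mesh.n_cells)})

    meta = {
        "region_names": mesh.region_names,
        "facet_sets": {k: np.asarray(v).tolist() for k, v in mesh.facet_sets.items()},
        "inner_facets_by_region": {k: np.asarray(v).tolist()
                                   for k, v in mesh.inner_facets_by_region.items()},
        "caps": [{"ring": c.ring.tolist(), "orientation": c.orientation,
                  "region": c.region, "kind": c.kind, "upstream": c.upstream}
                 for c in mesh.caps],
        "ties": {"slave_nodes": mesh.ties.slave_nodes.tolist(),
                 "master_nodes": mesh.ties.master_nodes.tolist(),
                 "weights": mesh.ties.weights.tolist()},
        "units": "m",
    }
    fd = ET.SubElement(piece, "FieldData")
    blob = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    _data_array(fd, "vesselmech_meta", blob, "UInt8")

    pts = ET.SubElement(piece, "Points")
    _data_array(pts, "Points", mesh.points, "Float64", 3)

    cells = ET.SubElement(piece, "Cells")
    _data_array(cells, "connectivity", mesh.cells, "Int64")
    _data_array(cells, "offsets", 8 * np.arange(1, mesh.n_cells + 1), "Int64")
    _data_array(cells, "types", np.full(mesh.n_cells, VTK_HEXAHEDRON), "UInt8")

    cd = ET.SubElement(piece, "CellData")
    _data_array(cd, "region", mesh.cell_region, "Int64")
    for name, arr in cell_data.items():
        arr = np.asarray(arr, dtype=float)
        _data_array(cd, name, arr, "Float64",
                    None if arr.ndim == 1 else arr.shape[1])

    if point_data:
        pd = ET.SubElement(piece, "PointData")
        for name, arr in point_data.items():
            arr = np.asarray(arr, dtype=float)
            _data_array(pd, name, arr, "Float64",
                        None if arr.ndim == 1 else arr.shape[1])

    ET.indent(root)
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="unicode")


def _find_data(parent: ET.Element | None, name: str) -> ET.Element | None:
    if parent is None:
        return None
    for el in parent.iter("DataArray"):
        if el.get("Name") == name:
            return el
    return None


def _parse_array(el: ET.Element, dtype) -> np.ndarray:
    tokens = (el.text or "").split()
    if not tokens:
        return np.zeros(0, dtype=dtype)
    return np.array(tokens, dtype=np.float64).astype(dtype)


def _read_vtu(path: Path) -> WallMesh:
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise MeshIOError(f"{path}: not a valid VTU/XML file ({exc})") from exc
    piece = tree.getroot().find(".//Piece")
    if piece is None:
        raise MeshIOError(f"{path}: no UnstructuredGrid Piece found")

    pts_el = _find_data(piece.find("Points"), "Points")
    if pts_el is None:
        raise MeshIOError(f"{path}: missing Points array")
    points = _parse_array(pts_el, float).reshape(-1, 3)

    conn_el = _find_data(piece.find("Cells"), "connectivity")
    types_el = _find_data(piece.find("Cells"), "types")
    if conn_el is None or types_el is None:
        raise MeshIOError(f"{path}: missing Cells connectivity/types arrays")
    types = _parse_array(types_el, np.int64)
    if np.any(types != VTK_HEXAHEDRON):
        raise MeshIOError(f"{path}: only hexahedral (type 12) cells are supported")
    cells = _parse_array(conn_el, np.int64).reshape(-1, 8)

    region_el = _find_data(piece.find("CellData"), "region")
    if region_el is None:
        raise MeshIOError(
            f"{path}: required cell-data array 'region' is missing")
    cell_region = _parse_array(region_el, np.int64)

    meta_el = _find_data(piece.find("FieldData"), "vesselmech_meta")
    if meta_el is None:
        raise MeshIOError(
            f"{path}: required field-data array 'vesselmech_meta' is missing "
            "(facet sets and region names)")
    meta = json.loads(bytes(_parse_array(meta_el, np.uint8)).decode())

    caps = [Cap(np.asarray(c["ring"], dtype=np.int64), int(c["orientation"]),
                c["region"], c["kind"], c.get("upstream"))
            for c in meta["caps"]]
    ties = Ties(np.asarray(meta["ties"]["slave_nodes"], dtype=np.int64),
                np.asarray(meta["ties"]["master_nodes"],
                           dtype=np.int64).reshape(-1, 4),
                np.asarray(meta["ties"]["weights"], dtype=float).reshape(-1, 4))
    facet_sets = {k: np.asarray(v, dtype=np.int64).reshape(-1, 4)
                  for k, v in meta["facet_sets"].items()}
    inner = {k: np.asarray(v, dtype=np.int64).reshape(-1, 4)
             for k, v in meta["inner_facets_by_region"].items()}
    return WallMesh(points, cells, cell_region, list(meta["region_names"]),
                    facet_sets, inner, caps, ties)


# ---------------------------------------------------------------------------
# STL (surface triangulation export)
# ---------------------------------------------------------------------------

def _write_stl(mesh: WallMesh, path: Path) -> None:
    quads = np.concatenate([mesh.facet_sets["inner_surface"],
                            mesh.facet_sets["outer_surface"]], axis=0)
    tris = np.concatenate([quads[:, [0, 1, 2]], quads[:, [0, 2, 3]]], axis=0)
    P = mesh.points
    with open(path, "w") as fh:
        fh.write("solid vesselmech\n")
        for tri in tris:
            a, b, c = P[tri]
            n = np.cross(b - a, c - a)
            nn = np.linalg.norm(n)
            n = n / nn if nn > 0 else n
            fh.write(f"  facet normal {n[0]:.9e} {n[1]:.9e} {n[2]:.9e}\n")
            fh.write("    outer loop\n")
            for v in (a, b, c):
                fh.write(f"      vertex {v[0]:.9e} {v[1]:.9e} {v[2]:.9e}\n")
            fh.write("    endloop\n  endfacet\n")
        fh.write("endsolid vesselmech\n")
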