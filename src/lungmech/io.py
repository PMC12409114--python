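"""Mesh and displacement-field file I/O.

Supported formats:

* STL (binary + ASCII, via trimesh) — surface-only input; a volume mesh is
  produced by Delaunay tetrahedralization of the surface vertices plus an
  interior point lattice (target edge length configurable).
* VTK legacy ASCII unstructured grid — labeled volume meshes; region labels
  carried in a cell-data field named ``region`` (0 = lung, 1 = tumor).
* Gmsh MSH v2.2 ASCII — labeled volume meshes; physical tag 1 = lung,
  2 = tumor.

Displacement fields travel as CSV with columns ``node_id, ux, uy, uz``.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import trimesh

from .mesh import (
    LUNG,
    TUMOR,
    MeshValidationError,
    TetMesh,
    boundary_edges,
    tet_signed_volumes,
)

_REGION_CODES = {LUNG: 0, TUMOR: 1}
_REGION_NAMES = {0: LUNG, 1: TUMOR}
_MSH_PHYSICAL = {LUNG: 1, TUMOR: 2}
_MSH_NAMES = {1: LUNG, 2: TUMOR}


class MeshFormatError(ValueError):
    """Raised on an unparseable mesh file; carries the failing byte offset."""

    def __init__(self, message: str, offset: int | None = None):
        if offset is not None:
            message = f"{message} (byte offset {offset})"
        super().__init__(message)
        self.offset = offset


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower()
    return {".stl": "stl", ".vtk": "vtk-legacy", ".msh": "msh"}.get(suffix, "")


def read_mesh(path, format: str | None = None, target_edge_length: float | None = None) -> TetMesh:
    """Read a mesh file into a :class:`TetMesh`.

    STL input is a closed surface; the interior is tetrahedralized with a
    Delaunay-based scheme (see :func:`tetrahedralize_surface`), so STL is
    only appropriate for convex or near-convex shapes.  VTK legacy and MSH
    carry the volume mesh and region labels directly.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    if fmt == "stl":
        surface = read_stl_surface(path)
        return tetrahedralize_surface(surface, target_edge_length=target_edge_length)
    if fmt == "vtk-legacy":
        return _read_vtk(path)
    if fmt == "msh":
        return _read_msh(path)
    raise MeshFormatError(f"unknown mesh format {fmt!r} for {path}")


def write_mesh(mesh: TetMesh, path, format: str | None = None) -> None:
    """Write a mesh; STL output carries the boundary surface only."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "stl":
        tm = trimesh.Trimesh(
            vertices=mesh.nodes, faces=mesh.surface_tris, process=False
        )
        tm.export(path)
    elif fmt == "vtk-legacy":
        _write_vtk(mesh, path)
    elif fmt == "msh":
        _write_msh(mesh, path)
    else:
        raise MeshFormatError(f"unknown mesh format {fmt!r} for {path}")


# -- STL ---------------------------------------------------------------------


def points_inside_surface(surface: trimesh.Trimesh, points: np.ndarray,
                          chunk: int = 4096) -> np.ndarray:
    """Point-in-closed-surface test by generalized winding number.

    Sums the signed solid angle of every triangle (van Oosterom-Strackee)
    per query point; the total is ~4*pi inside a watertight surface and ~0
    outside.  Exact up to floating point for closed orientable surfaces
    and free of ray/edge degeneracies.
    """
    tris = surface.triangles  # (F, 3, 3)
    points = np.asarray(points, dtype=float)
    out = np.empty(len(points), dtype=bool)
    for start in range(0, len(points), chunk):
        p = points[start : start + chunk]
        A = tris[None, :, 0, :] - p[:, None, :]
        B = tris[None, :, 1, :] - p[:, None, :]
        C = tris[None, :, 2, :] - p[:, None, :]
        la = np.linalg.norm(A, axis=-1)
        lb = np.linalg.norm(B, axis=-1)
        lc = np.linalg.norm(C, axis=-1)
        det = np.einsum("pfi,pfi->pf", A, np.cross(B, C))
        denom = (
            la * lb * lc
            + np.einsum("pfi,pfi->pf", A, B) * lc
            + np.einsum("pfi,pfi->pf", B, C) * la
            + np.einsum("pfi,pfi->pf", C, A) * lb
        )
        omega = 2.0 * np.arctan2(det, denom)
        out[start : start + chunk] = omega.sum(axis=1) > 2.0 * np.pi
    return out


def read_stl_surface(path) -> trimesh.Trimesh:
    """Load an STL surface and require it to be closed."""
    try:
        tm = trimesh.load_mesh(Path(path), file_type="stl", process=True)
    except Exception as exc:  # trimesh raises assorted types on bad input
        raise MeshFormatError(f"cannot parse STL {path}: {exc}", offset=0) from exc
    if not isinstance(tm, trimesh.Trimesh) or len(tm.faces) == 0:
        raise MeshFormatError(f"STL {path} contains no triangles", offset=0)
    if not tm.is_watertight:
        edges = tm.edges_sorted
        uniq, counts = np.unique(edges, axis=0, return_counts=True)
        bad = uniq[counts != 2]
        raise MeshValidationError(
            f"STL surface not watertight: {len(bad)} boundary edges, first few "
            f"{bad[:5].tolist()}"
        )
    if tm.volume < 0:
        tm.invert()
    return tm


def tetrahedralize_surface(
    surface: trimesh.Trimesh,
    target_edge_length: float | None = None,
    region: str = LUNG,
) -> TetMesh:
    """Fill a closed surface with tetrahedra via Delaunay triangulation.

    Surface vertices plus an interior cubic lattice (spacing =
    ``target_edge_length``, default bounding-box diagonal / 40) are
    Delaunay-triangulated; tets whose centroid falls outside the surface are
    discarded.  Exact for convex shapes; near-convex shapes may gain small
    sliver overhangs, reported through the usual geometry QC.
    """
    from scipy.spatial import Delaunay, cKDTree

    lo, hi = surface.bounds
    if target_edge_length is None:
        target_edge_length = float(np.linalg.norm(hi - lo)) / 40.0
    h = target_edge_length
    axes = [np.arange(lo[i] + h / 2, hi[i], h) for i in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    # keep lattice points safely interior so surface triangles stay intact
    inside = points_inside_surface(surface, grid)
    interior = grid[inside]
    if len(interior):
        skin = cKDTree(np.vstack([surface.vertices,
                                  surface.triangles_center]))
        dist, _ = skin.query(interior)
        interior = interior[dist > 0.45 * h]
    points = np.vstack([surface.vertices, interior])
    # deterministic sub-micron jitter breaks co-spherical degeneracies that
    # would otherwise yield zero-volume Delaunay slivers
    rng = np.random.default_rng(0)
    points = points + rng.normal(0.0, 1e-4 * h, size=points.shape)
    delaunay = Delaunay(points)
    tets = delaunay.simplices
    centroids = points[tets].mean(axis=1)
    keep = points_inside_surface(surface, centroids)
    tets = tets[keep]
    if len(tets) == 0:
        raise MeshValidationError("tetrahedralization produced no interior tets")
    mesh = TetMesh(
        nodes=points,
        tets=tets,
        region=np.full(len(tets), region, dtype=object),
    )
    mesh.validate()
    return mesh


# -- VTK legacy --------------------------------------------------------------


def _read_vtk(path: Path) -> TetMesh:
    text = Path(path).read_text()
    tokens = []
    offsets = []
    pos = 0
    for line in text.splitlines(keepends=True):
        stripped = line.split("#", 1)[0]
        col = 0
        for tok in stripped.split():
            offsets.append(pos + stripped.index(tok, col))
            col = stripped.index(tok, col) + len(tok)
            tokens.append(tok)
        pos += len(line)
    i = 0

    def fail(msg):
        off = offsets[i] if i < len(offsets) else len(text)
        raise MeshFormatError(f"VTK parse error in {path}: {msg}", offset=off)

    def expect(word):
        nonlocal i
        if i >= len(tokens) or tokens[i].upper() != word:
            fail(f"expected {word}")
        i += 1

    def take(n, cast):
        nonlocal i
        if i + n > len(tokens):
            fail(f"unexpected end of file ({n} values needed)")
        try:
            vals = [cast(t) for t in tokens[i : i + n]]
        except ValueError:
            fail("bad numeric value")
        i += n
        return vals

    # header: "# vtk DataFile ..." was stripped as comment; find DATASET
    while i < len(tokens) and tokens[i].upper() != "DATASET":
        i += 1
    expect("DATASET")
    if i >= len(tokens) or tokens[i].upper() != "UNSTRUCTURED_GRID":
        fail("expected UNSTRUCTURED_GRID dataset")
    i += 1
    expect("POINTS")
    (n_pts,) = take(1, int)
    i += 1  # dtype word
    nodes = np.array(take(3 * n_pts, float)).reshape(n_pts, 3)
    expect("CELLS")
    n_cells, n_ints = take(2, int)
    raw = take(n_ints, int)
    cells = []
    k = 0
    for _ in range(n_cells):
        cnt = raw[k]
        cells.append(raw[k + 1 : k + 1 + cnt])
        k += 1 + cnt
    expect("CELL_TYPES")
    (n_types,) = take(1, int)
    types = take(n_types, int)
    if n_types != n_cells:
        fail("CELL_TYPES count mismatch")
    tets = [c for c, t in zip(cells, types) if t == 10]
    if not tets:
        fail("no tetrahedral (type 10) cells")
    region = np.full(len(tets), LUNG, dtype=object)
    while i < len(tokens):
        word = tokens[i].upper()
        if word == "CELL_DATA":
            i += 1
            take(1, int)
        elif word == "SCALARS":
            name = tokens[i + 1]
            i += 3  # SCALARS name dtype [numComp]
            if i < len(tokens) and tokens[i].isdigit():
                i += 1
            expect("LOOKUP_TABLE")
            i += 1  # table name
            vals = take(n_cells, int)
            if name == "region":
                tet_vals = [v for v, t in zip(vals, types) if t == 10]
                region = np.array(
                    [_REGION_NAMES.get(v, LUNG) for v in tet_vals], dtype=object
                )
        else:
            i += 1
    return TetMesh(nodes=nodes, tets=np.array(tets, dtype=np.int64), region=region)


def _write_vtk(mesh: TetMesh, path: Path) -> None:
    buf = _io.StringIO()
    buf.write("# vtk DataFile Version 3.0\nlungmech tetrahedral mesh\nASCII\n")
    buf.write("DATASET UNSTRUCTURED_GRID\n")
    buf.write(f"POINTS {len(mesh.nodes)} double\n")
    np.savetxt(buf, mesh.nodes, fmt="%.9g")
    n = len(mesh.tets)
    buf.write(f"CELLS {n} {5 * n}\n")
    np.savetxt(
        buf,
        np.column_stack([np.full(n, 4, dtype=np.int64), mesh.tets]),
        fmt="%d",
    )
    buf.write(f"CELL_TYPES {n}\n")
    buf.write("\n".join(["10"] * n) + "\n")
    buf.write(f"CELL_DATA {n}\nSCALARS region int 1\nLOOKUP_TABLE default\n")
    codes = [str(_REGION_CODES[r]) for r in mesh.region]
    buf.write("\n".join(codes) + "\n")
    Path(path).write_text(buf.getvalue())


def write_vtk_solution(mesh: TetMesh, path, point_vectors=None, cell_tensors=None,
                       cell_scalars=None) -> None:
    """Write a VTK legacy file with optional solution fields attached.

    ``point_vectors``/``cell_tensors``/``cell_scalars`` map field names to
    arrays of shape (N,3), (M,3,3) and (M,) respectively.
    """
    _write_vtk(mesh, path)
    with open(path, "a") as fh:
        if point_vectors:
            fh.write(f"POINT_DATA {len(mesh.nodes)}\n")
            for name, arr in point_vectors.items():
                fh.write(f"VECTORS {name} double\n")
                np.savetxt(fh, np.asarray(arr), fmt="%.9g")
        if cell_tensors or cell_scalars:
            for name, arr in (cell_tensors or {}).items():
                fh.write(f"TENSORS {name} double\n")
                np.savetxt(fh, np.asarray(arr).reshape(len(mesh.tets), 9), fmt="%.9g")
            for name, arr in (cell_scalars or {}).items():
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                np.savetxt(fh, np.asarray(arr), fmt="%.9g")


# -- Gmsh MSH v2.2 -----------------------------------------------------------


def _read_msh(path: Path) -> TetMesh:
    text = Path(path).read_text()
    lines = text.splitlines()
    offsets = np.cumsum([0] + [len(l) + 1 for l in lines])

    def fail(idx, msg):
        raise MeshFormatError(f"MSH parse error in {path}: {msg}", offset=int(offsets[idx]))

    def section(name):
        try:
            start = lines.index(f"${name}")
            end = lines.index(f"$End{name}")
        except ValueError:
            fail(0, f"missing ${name} section")
        return start + 1, end

    s, _ = section("MeshFormat")
    if not lines[s].startswith("2.2"):
        fail(s, f"unsupported MSH version {lines[s].split()[0]!r} (need 2.2)")

    s, e = section("Nodes")
    n_nodes = int(lines[s])
    if e - s - 1 != n_nodes:
        fail(s, "node count mismatch")
    ids = np.empty(n_nodes, dtype=np.int64)
    coords = np.empty((n_nodes, 3))
    for k in range(n_nodes):
        parts = lines[s + 1 + k].split()
        if len(parts) != 4:
            fail(s + 1 + k, "bad node line")
        ids[k] = int(parts[0])
        coords[k] = [float(v) for v in parts[1:]]
    order = np.argsort(ids)
    coords = coords[order]
    id_to_idx = {int(ids[o]): j for j, o in enumerate(order)}

    s, e = section("Elements")
    tets, region = [], []
    for k in range(s + 1, e):
        parts = [int(v) for v in lines[k].split()]
        etype, ntags = parts[1], parts[2]
        tags = parts[3 : 3 + ntags]
        conn = parts[3 + ntags :]
        if etype == 4:  # 4-node tetrahedron
            if len(conn) != 4:
                fail(k, "tet element without 4 nodes")
            tets.append([id_to_idx[c] for c in conn])
            phys = tags[0] if tags else 1
            region.append(_MSH_NAMES.get(phys, LUNG))
    if not tets:
        fail(0, "no tetrahedral elements")
    return TetMesh(
        nodes=coords,
        tets=np.array(tets, dtype=np.int64),
        region=np.array(region, dtype=object),
    )


def _write_msh(mesh: TetMesh, path: Path) -> None:
    buf = _io.StringIO()
    buf.write("$MeshFormat\n2.2 0 8\n$EndMeshFormat\n")
    buf.write(f"$Nodes\n{len(mesh.nodes)}\n")
    for i, (x, y, z) in enumerate(mesh.nodes, start=1):
        buf.write(f"{i} {x:.9g} {y:.9g} {z:.9g}\n")
    buf.write("$EndNodes\n")
    buf.write(f"$Elements\n{len(mesh.tets)}\n")
    for e, (tet, reg) in enumerate(zip(mesh.tets, mesh.region), start=1):
        phys = _MSH_PHYSICAL[reg]
        conn = " ".join(str(int(c) + 1) for c in tet)
        buf.write(f"{e} 4 2 {phys} {phys} {conn}\n")
    buf.write("$EndElements\n")
    Path(path).write_text(buf.getvalue())


# -- displacement fields -----------------------------------------------------


def write_displacement_csv(path, node_ids: np.ndarray, displacements: np.ndarray) -> None:
    """Write a surface displacement field as ``node_id,ux,uy,uz`` CSV."""
    arr = np.column_stack([np.asarray(node_ids, dtype=float), displacements])
    np.savetxt(path, arr, delimiter=",", header="node_id,ux,uy,uz",
               comments="", fmt=["%d", "%.12g", "%.12g", "%.12g"])


def read_displacement_csv(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a ``node_id,ux,uy,uz`` CSV; returns (node_ids, (K,3) array in mm)."""
    arr = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    if arr.shape[1] != 4:
        raise MeshFormatError(f"displacement CSV {path} must have 4 columns")
    return arr[:, 0].astype(np.int64), arr[:, 1:4]
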