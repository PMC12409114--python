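"""Tetrahedral mesh data structures and geometry computations.

Meshes are labeled lung/tumor tetrahedral volumes in DICOM LPS coordinates,
millimetres, 0-based node indexing.  Tets follow the convention that the
signed volume ``det([b-a, c-a, d-a]) / 6`` is positive; meshes violating it
are repaired on construction by swapping two vertices (logged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

LUNG = "lung"
TUMOR = "tumor"


class MeshValidationError(ValueError):
    """Raised when a mesh violates a structural invariant."""


def tet_signed_volumes(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Signed volume of each tetrahedron (positive for the fixed convention)."""
    a, b, c, d = (nodes[tets[:, i]] for i in range(4))
    return np.einsum("ij,ij->i", np.cross(b - a, c - a), d - a) / 6.0


def triangle_areas(nodes: np.ndarray, tris: np.ndarray) -> np.ndarray:
    a, b, c = (nodes[tris[:, i]] for i in range(3))
    return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)


def triangle_normals(nodes: np.ndarray, tris: np.ndarray) -> np.ndarray:
    """Unit normals following the triangle winding order."""
    a, b, c = (nodes[tris[:, i]] for i in range(3))
    n = np.cross(b - a, c - a)
    norms = np.linalg.norm(n, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise MeshValidationError("degenerate (zero-area) surface triangle")
    return n / norms


def enclosed_volume(nodes: np.ndarray, tris: np.ndarray) -> float:
    """Signed volume enclosed by an oriented triangulated surface.

    Divergence theorem: V = (1/6) sum_f a . (b x c).  Positive for
    outward-oriented closed surfaces.
    """
    a, b, c = (nodes[tris[:, i]] for i in range(3))
    return float(np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0)


def surface_edges(tris: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Undirected edges of a triangulation and their multiplicities."""
    e = np.vstack([tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [2, 0]]])
    e = np.sort(e, axis=1)
    return np.unique(e, axis=0, return_counts=True)


def is_closed_surface(tris: np.ndarray) -> bool:
    _, counts = surface_edges(tris)
    return bool(np.all(counts == 2))


def boundary_edges(tris: np.ndarray) -> np.ndarray:
    """Edges not shared by exactly two triangles (empty for a closed surface)."""
    edges, counts = surface_edges(tris)
    return edges[counts != 2]


_TET_FACES = np.array([[1, 2, 3], [0, 3, 2], [0, 1, 3], [0, 2, 1]])
# Face i is opposite vertex i, wound so its normal points out of the tet
# (for positively oriented tets).


def extract_surface(tets: np.ndarray) -> np.ndarray:
    """Outward-oriented boundary triangles of a tet mesh (faces used once)."""
    faces = tets[:, _TET_FACES].reshape(-1, 3)
    key = np.sort(faces, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    return faces[counts[inv] == 1]


@dataclass
class TetMesh:
    """Labeled tetrahedral lung(+tumor) mesh with an oriented boundary surface.

    Parameters
    ----------
    nodes : (N, 3) float array, mm, DICOM LPS.
    tets : (M, 4) int array of node indices, positively oriented.
    region : (M,) array of labels, each ``"lung"`` or ``"tumor"``.
    surface_tris : (K, 3) int array, outward-oriented closed boundary;
        recomputed from ``tets`` when omitted.
    phase_id : respiratory-phase tag, e.g. ``"P50"``.
    """

    nodes: np.ndarray
    tets: np.ndarray
    region: np.ndarray
    surface_tris: np.ndarray | None = None
    phase_id: str = ""

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.tets = np.asarray(self.tets, dtype=np.int64)
        self.region = np.asarray(self.region)
        if self.nodes.ndim != 2 or self.nodes.shape[1] != 3:
            raise MeshValidationError("nodes must be (N, 3)")
        if self.tets.ndim != 2 or self.tets.shape[1] != 4:
            raise MeshValidationError("tets must be (M, 4)")
        if self.region.shape != (len(self.tets),):
            raise MeshValidationError("region must be one label per tet")
        if self.tets.size and (self.tets.min() < 0 or self.tets.max() >= len(self.nodes)):
            raise MeshValidationError("tet node index out of range")
        self._repair_orientation()
        if self.surface_tris is None:
            self.surface_tris = extract_surface(self.tets)
        else:
            self.surface_tris = np.asarray(self.surface_tris, dtype=np.int64)

    def _repair_orientation(self) -> None:
        vols = tet_signed_volumes(self.nodes, self.tets)
        flipped = vols < 0
        if np.any(flipped):
            logger.info("repairing orientation of %d inverted tets", int(flipped.sum()))
            self.tets = self.tets.copy()
            self.tets[flipped, 1], self.tets[flipped, 2] = (
                self.tets[flipped, 2].copy(),
                self.tets[flipped, 1].copy(),
            )
        if np.any(tet_signed_volumes(self.nodes, self.tets) <= 0):
            raise MeshValidationError("degenerate (zero-volume) tetrahedron")

    # -- derived quantities -------------------------------------------------

    def region_mask(self, region: str | None) -> np.ndarray:
        if region is None:
            return np.ones(len(self.tets), dtype=bool)
        mask = self.region == region
        if not mask.any():
            raise MeshValidationError(f"region {region!r} is empty")
        return mask

    def volume(self, region: str | None = None) -> float:
        """Total volume (mm^3) of all tets, or of one labeled region."""
        vols = tet_signed_volumes(self.nodes, self.tets)
        return float(vols[self.region_mask(region)].sum())

    def centroid(self, region: str | None = None) -> np.ndarray:
        """Volume-weighted centroid (mm) of a region."""
        mask = self.region_mask(region)
        vols = tet_signed_volumes(self.nodes, self.tets)[mask]
        if vols.sum() <= 0:
            raise MeshValidationError("zero-volume region")
        centers = self.nodes[self.tets[mask]].mean(axis=1)
        return (vols[:, None] * centers).sum(axis=0) / vols.sum()

    def surface_area(self) -> float:
        return float(triangle_areas(self.nodes, self.surface_tris).sum())

    def enclosed_volume(self) -> float:
        return enclosed_volume(self.nodes, self.surface_tris)

    def is_watertight(self) -> bool:
        return is_closed_surface(self.surface_tris)

    def surface_nodes(self) -> np.ndarray:
        """Sorted unique node indices on the boundary surface."""
        return np.unique(self.surface_tris)

    def bounding_box(self, region: str | None = None) -> tuple[np.ndarray, np.ndarray]:
        mask = self.region_mask(region)
        pts = self.nodes[np.unique(self.tets[mask])]
        return pts.min(axis=0), pts.max(axis=0)

    def translated(self, offset) -> "TetMesh":
        return replace(self, nodes=self.nodes + np.asarray(offset, dtype=float))

    def with_nodes(self, nodes: np.ndarray) -> "TetMesh":
        """Same topology with new node coordinates (re-validated)."""
        return TetMesh(
            nodes=np.asarray(nodes, dtype=float),
            tets=self.tets,
            region=self.region,
            surface_tris=self.surface_tris,
            phase_id=self.phase_id,
        )

    def submesh(self, region: str) -> "TetMesh":
        """Extract one region as a standalone mesh (nodes renumbered)."""
        mask = self.region_mask(region)
        tets = self.tets[mask]
        used = np.unique(tets)
        remap = np.full(len(self.nodes), -1, dtype=np.int64)
        remap[used] = np.arange(len(used))
        return TetMesh(
            nodes=self.nodes[used],
            tets=remap[tets],
            region=self.region[mask],
            phase_id=self.phase_id,
        )

    def validate(self) -> None:
        """Check the full invariant set; raise MeshValidationError on failure."""
        if not self.is_watertight():
            bad = boundary_edges(self.surface_tris)
            raise MeshValidationError(
                f"surface not closed: {len(bad)} boundary edges, first few "
                f"{bad[:5].tolist()}"
            )
        if self.enclosed_volume() <= 0:
            raise MeshValidationError("surface is not outward-oriented")


@dataclass
class GeometryQC:
    """Geometric agreement report between two meshes of the same anatomy."""

    surface_area: float
    volume: float
    rel_area_diff: float
    rel_vol_diff: float
    watertight: bool

    def passed(self, tol: float = 0.02) -> bool:
        """All relative discrepancies below ``tol`` and surface closed."""
        return self.watertight and self.rel_area_diff < tol and self.rel_vol_diff < tol


def mesh_volume(mesh: TetMesh, region: str | None = None) -> float:
    """Volume in mm^3 of the mesh or of one labeled region."""
    return mesh.volume(region)


def mesh_centroid(mesh: TetMesh, region: str | None = None) -> np.ndarray:
    """Volume-weighted centroid in mm of the mesh or of one labeled region."""
    return mesh.centroid(region)


def geometry_qc(mesh_a: TetMesh, mesh_b: TetMesh) -> GeometryQC:
    """Compare surface area and volume of mesh_a against reference mesh_b.

    Relative differences are |a - b| / b, mirroring the mask-vs-STL
    consistency check used when meshes are rebuilt from segmentations.
    """
    area_a, area_b = mesh_a.surface_area(), mesh_b.surface_area()
    vol_a, vol_b = mesh_a.volume(), mesh_b.volume()
    if vol_a <= 0 or vol_b <= 0 or area_a <= 0 or area_b <= 0:
        raise MeshValidationError("areas and volumes must be strictly positive")
    return GeometryQC(
        surface_area=area_a,
        volume=vol_a,
        rel_area_diff=abs(area_a - area_b) / area_b,
        rel_vol_diff=abs(vol_a - vol_b) / vol_b,
        watertight=mesh_a.is_watertight() and mesh_b.is_watertight(),
    )


def mesh_convergence_report(meshes, boundary_maps, solve) -> list[dict]:
    """Report tumor-displacement change across mesh densities.

    Parameters
    ----------
    meshes : sequence of TetMesh at increasing density.
    boundary_maps : callable(nodes) -> displacement for each mesh's surface.
    solve : callable(mesh, boundary) -> object with tumor centroid displacement
        accessor ``tumor_centroid_displacement`` (mm, 3-vector).

    Returns one dict per mesh with tet count and displacement, plus the
    relative change from the previous density.
    """
    report = []
    prev = None
    for mesh in meshes:
        disp = solve(mesh, boundary_maps(mesh))
        d = np.asarray(disp.tumor_centroid_displacement, dtype=float)
        entry = {"n_tets": int(len(mesh.tets)), "tumor_disp_mm": d.tolist()}
        if prev is not None:
            denom = max(np.linalg.norm(prev), 1e-12)
            entry["rel_change"] = float(np.linalg.norm(d - prev) / denom)
        report.append(entry)
        prev = d
    return report
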