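"""Lung-surface traction vector fields and their relation to tumor motion.

The nominal (first Piola-Kirchhoff) traction on the undeformed lung
surface is ``T = P n0`` per boundary face, with ``P`` taken from the
single adjacent tetrahedron (piecewise-constant stress for linear
elements).  The Cauchy stress ``sigma = J^-1 P F^T`` accompanies each
face, and ``theta`` is the angle between T and the outward reference
normal.  Directional summaries aggregate |T| and theta over faces inside
an angular cone around rays cast from the end-expiration tumor centroid
G50: toward the true end-inspiration centroid (t), the simulated one (s),
and the nearest lung-surface point (l).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .fem import FEMSolution
from .mesh import TetMesh, triangle_areas, triangle_normals


@dataclass
class TractionField:
    """Per-surface-face nominal traction in the reference configuration.

    ``T`` is the constitutive face traction P n0 with P from the single
    adjacent tetrahedron.  ``T_consistent`` is the energy-conjugate
    boundary flux recovered from the Dirichlet reaction forces and
    distributed over the incident faces; it satisfies the discrete global
    equilibrium identity (zero net surface force without body forces) to
    solver tolerance, which the piecewise-constant face stress only
    approaches at O(h).
    """

    faces: np.ndarray            # (K, 3) node indices
    centroids: np.ndarray        # (K, 3) face centroids, mm
    n0: np.ndarray               # (K, 3) outward unit reference normals
    area: np.ndarray             # (K,) reference areas, mm^2
    T: np.ndarray                # (K, 3) nominal traction, Pa
    sigma: np.ndarray            # (K, 3, 3) Cauchy stress, Pa
    theta: np.ndarray            # (K,) angle(T, n0), degrees
    T_consistent: np.ndarray = None   # (K, 3) reaction-based traction, Pa

    @property
    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.T, axis=1)

    def equilibrium_residual(self, flux: str = "consistent") -> float:
        """|sum T*dA| / sum |T|*dA over the closed surface.

        ``flux="consistent"`` (default) uses the reaction-based traction,
        for which the identity is exact up to the Newton residual;
        ``flux="face"`` reports the O(h) consistency error of the
        adjacent-tet stress.
        """
        T = self.T_consistent if flux == "consistent" else self.T
        total = (T * self.area[:, None]).sum(axis=0)
        scale = float((np.linalg.norm(T, axis=1) * self.area).sum())
        if scale == 0.0:
            return 0.0
        return float(np.linalg.norm(total) / scale)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cx": self.centroids[:, 0],
                "cy": self.centroids[:, 1],
                "cz": self.centroids[:, 2],
                "Tx": self.T[:, 0],
                "Ty": self.T[:, 1],
                "Tz": self.T[:, 2],
                "magnitude_Pa": self.magnitude,
                "theta_deg": self.theta,
                "area_mm2": self.area,
            }
        )


def _face_to_tet(mesh: TetMesh) -> np.ndarray:
    """Adjacent tet index for every boundary face of the mesh."""
    from .mesh import _TET_FACES

    all_faces = mesh.tets[:, _TET_FACES].reshape(-1, 3)
    owner = np.repeat(np.arange(len(mesh.tets)), 4)
    key = {tuple(sorted(f)): o for f, o in zip(all_faces.tolist(), owner)}
    return np.array([key[tuple(sorted(f))] for f in mesh.surface_tris.tolist()])


def _consistent_face_tractions(solution: FEMSolution, mesh: TetMesh,
                               tris: np.ndarray, area: np.ndarray) -> np.ndarray:
    """Reaction-based nominal tractions distributed over surface faces.

    Nodal internal forces R_a = sum_e V_e P_e grad(N_a) vanish at interior
    (free) nodes of a converged solve; at constrained surface nodes they
    are the Dirichlet reactions.  Each node's reaction is split over its
    incident surface faces in proportion to face area (1/3 lumping), so
    sum_f T_f A_f = sum_a R_a exactly.
    """
    from .mesh import tet_signed_volumes

    nodes, tets = mesh.nodes, mesh.tets
    vols = tet_signed_volumes(nodes, tets)
    edges = nodes[tets[:, 1:]] - nodes[tets[:, :1]]
    Dinv = np.linalg.inv(np.swapaxes(edges, 1, 2))
    grads = np.empty((len(tets), 4, 3))
    grads[:, 1:, :] = Dinv
    grads[:, 0, :] = -Dinv.sum(axis=1)
    f = np.einsum("m,miJ,maJ->mai", vols, solution.P, grads)
    reactions = np.zeros((len(nodes), 3))
    np.add.at(reactions, tets, f)

    # area share of each node over its incident surface faces
    node_area = np.zeros(len(nodes))
    np.add.at(node_area, tris, np.repeat(area[:, None] / 3.0, 3, axis=1))
    share = (area[:, None] / 3.0) / node_area[tris]        # (K, 3)
    face_force = np.einsum("ka,kai->ki", share, reactions[tris])
    return face_force / area[:, None]


def traction_field(solution: FEMSolution, mesh: TetMesh | None = None) -> TractionField:
    """Compute the surface traction field of a converged solution."""
    if not solution.converged:
        raise ValueError("traction field requires a converged solution")
    mesh = mesh or solution.mesh
    tris = mesh.surface_tris
    n0 = triangle_normals(mesh.nodes, tris)
    area = triangle_areas(mesh.nodes, tris)
    owners = _face_to_tet(mesh)
    P = solution.P[owners]
    F = solution.F[owners]
    T = np.einsum("kij,kj->ki", P, n0)
    J = np.linalg.det(F)[:, None, None]
    sigma = P @ np.swapaxes(F, 1, 2) / J
    mag = np.linalg.norm(T, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.einsum("ki,ki->k", T, n0) / np.where(mag > 0, mag, 1.0)
    theta = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    theta[mag == 0] = 0.0
    return TractionField(
        faces=tris,
        centroids=mesh.nodes[tris].mean(axis=1),
        n0=n0,
        area=area,
        T=T,
        sigma=sigma,
        theta=theta,
        T_consistent=_consistent_face_tractions(solution, mesh, tris, area),
    )


@dataclass
class DirectionalSample:
    """Cone-aggregated traction along one probe direction."""

    direction: np.ndarray        # unit vector from G50
    amplitude: float             # area-weighted mean |T| in the cone, Pa
    angle: float                 # area-weighted mean theta in the cone, deg
    n_faces: int


@dataclass
class DirectionalSummary:
    """Traction summaries along the t (true), s (simulated) and l (nearest
    lung surface) directions from the end-expiration tumor centroid."""

    t: DirectionalSample
    s: DirectionalSample
    l: DirectionalSample

    def as_dict(self) -> dict:
        out = {}
        for name in ("t", "s", "l"):
            sample = getattr(self, name)
            out[f"amplitude_{name}"] = sample.amplitude
            out[f"angle_{name}"] = sample.angle
        return out


def _cone_sample(field: TractionField, origin, direction, cone_deg: float) -> DirectionalSample:
    d = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(d)
    if norm == 0:
        raise ValueError("degenerate (zero-length) probe direction")
    d = d / norm
    rel = field.centroids - origin
    rel_norm = np.linalg.norm(rel, axis=1)
    with np.errstate(invalid="ignore"):
        cosang = (rel @ d) / np.where(rel_norm > 0, rel_norm, 1.0)
    in_cone = cosang >= np.cos(np.radians(cone_deg))
    if not in_cone.any():
        # a ray from inside a closed surface always exits; on coarse meshes
        # the cone may contain no face centroid, so take the best-aligned one
        in_cone = cosang == cosang.max()
    w = field.area[in_cone]
    mags = field.magnitude[in_cone]
    thetas = field.theta[in_cone]
    return DirectionalSample(
        direction=d,
        amplitude=float((w * mags).sum() / w.sum()),
        angle=float((w * thetas).sum() / w.sum()),
        n_faces=int(in_cone.sum()),
    )


def directional_summary(field: TractionField, tumor_centroids: dict,
                        lung_mesh: TetMesh, cone_deg: float = 10.0) -> DirectionalSummary:
    """Aggregate traction along the three probe directions of the motion
    analysis.

    ``tumor_centroids`` maps ``"G50"``, ``"G00_true"`` and ``"G00_sim"`` to
    3-vectors (mm).  Each direction defines a ray from G50; the summary is
    the area-weighted mean of |T| and theta over surface faces within
    ``cone_deg`` of the ray.
    """
    g50 = np.asarray(tumor_centroids["G50"], dtype=float)
    for key in ("G50", "G00_true", "G00_sim"):
        if not np.all(np.isfinite(tumor_centroids[key])):
            raise ValueError(f"centroid {key} must be finite")
    # nearest lung-surface point from G50 (by face-centroid distance)
    rel = field.centroids - g50
    nearest = field.centroids[int(np.argmin(np.linalg.norm(rel, axis=1)))]
    dirs = {
        "t": np.asarray(tumor_centroids["G00_true"], dtype=float) - g50,
        "s": np.asarray(tumor_centroids["G00_sim"], dtype=float) - g50,
        "l": nearest - g50,
    }
    samples = {k: _cone_sample(field, g50, v, cone_deg) for k, v in dirs.items()}
    return DirectionalSummary(t=samples["t"], s=samples["s"], l=samples["l"])


def correlate_traction_motion(summaries, motion_amplitudes) -> pd.DataFrame:
    """Correlate cone-aggregated traction with tumor motion across cases.

    For each direction (t, s, l) and each quantity (amplitude, angle),
    returns the Pearson r with a two-sided p-value and the R^2 of the
    ordinary least-squares line.  Requires >= 3 cases and nonzero variance
    in every variable.
    """
    amp = np.asarray(motion_amplitudes, dtype=float)
    if len(summaries) != len(amp) or len(amp) < 3:
        raise ValueError("need >= 3 paired cases")
    if np.var(amp) == 0:
        raise ValueError("tumor motion amplitudes have zero variance")
    rows = []
    table = pd.DataFrame([s.as_dict() for s in summaries])
    for col in table.columns:
        y = table[col].to_numpy()
        if np.var(y) == 0:
            raise ValueError(f"zero variance in {col}: correlation undefined")
        r, p = stats.pearsonr(amp, y)
        direction, quantity = col.split("_")[1], col.split("_")[0]
        rows.append(
            {
                "direction": direction,
                "quantity": quantity,
                "pearson_r": float(r),
                "p_value": float(p),
                "r_squared": float(r**2),
            }
        )
    return pd.DataFrame(rows)
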