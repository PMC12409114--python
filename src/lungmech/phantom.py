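"""Seeded breathing phantoms with analytic ground truth.

The phantom stands in for the 4DCT pathway: an ellipsoidal "lung" with an
embedded spherical "tumor" is carried through a 10-phase breathing cycle by
a smooth, analytically invertible displacement map

    u(x, t) = s(t) * d(x),      s(t) = (1 + cos(2*pi*t / T)) / 2,

so phase P00 (t = 0) is end-inspiration (s = 1) and P50 (t = T/2) is the
undeformed end-expiration reference (s = 0).  The spatial part d(x) is an
anisotropic dilation about the lung center plus a caudally graded axial
term mimicking diaphragm drive; the grading is constructed so the enclosed
volume depends only on the dilation part, which lets the inhale/exhale
volume ratio J = V(P00)/V(P50) be prescribed exactly.

Ground-truth elasticity trajectories E(t), v(t) are first-order Fourier
series inside the physiological boxes [2, 11] kPa and [0.1, 0.49], so the
temporal-fitting stage can recover them exactly in the noise-free case.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import trimesh
from scipy.optimize import brentq
from scipy.spatial import Delaunay

from . import io as mio
from .mesh import LUNG, TUMOR, MeshValidationError, TetMesh

E_BOUNDS_KPA = (2.0, 11.0)
V_BOUNDS = (0.1, 0.49)


class PhantomSpecError(ValueError):
    """Invalid phantom specification."""


@dataclass
class PhantomSpec:
    """Breathing-phantom parameters (lengths in mm, times in seconds).

    Defaults follow typical free-breathing lung-cancer patients: a 4 s
    cycle, a 13% inhale volume change, a ~4 cm^3 tumor sitting caudally
    where diaphragm-driven motion is largest, and Fourier-type elasticity
    trajectories centered mid-box.
    """

    lung_semiaxes: tuple[float, float, float] = (50.0, 70.0, 100.0)
    tumor_center: tuple[float, float, float] = (0.0, 0.0, -40.0)
    tumor_radius: float = 10.0
    n_phases: int = 10
    cycle_period: float = 4.0
    max_volume_change: float = 0.13
    displacement_amplitude: float = 8.0
    e_coeffs: tuple[float, float, float] = (6.5, 2.0, 1.0)   # kPa: a0, a1*cos, b1*sin
    v_coeffs: tuple[float, float, float] = (0.30, 0.08, 0.04)
    axis_weights: tuple[float, float, float] = (0.25, 0.25, 1.0)
    mesh_edge_length: float = 16.0
    lung_subdivisions: int = 2
    tumor_subdivisions: int = 1
    noise_sigma: float = 0.0
    hu_mass_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        a = np.asarray(self.lung_semiaxes, dtype=float)
        c = np.asarray(self.tumor_center, dtype=float)
        if np.any(a <= 0) or self.tumor_radius <= 0:
            raise PhantomSpecError("semiaxes and tumor radius must be positive")
        # conservative strict-containment test
        if np.linalg.norm(c / a) + self.tumor_radius / a.min() >= 0.95:
            raise PhantomSpecError("tumor must lie strictly inside the lung")
        if not 0 < self.max_volume_change <= 0.4:
            raise PhantomSpecError("max_volume_change must be in (0, 0.4]")
        t = np.linspace(0, self.cycle_period, 201)
        E, v = self.elasticity_truth(t)
        if E.min() < E_BOUNDS_KPA[0] or E.max() > E_BOUNDS_KPA[1]:
            raise PhantomSpecError(
                f"E(t) range [{E.min():.3g}, {E.max():.3g}] kPa leaves "
                f"{list(E_BOUNDS_KPA)} kPa"
            )
        if v.min() < V_BOUNDS[0] or v.max() > V_BOUNDS[1]:
            raise PhantomSpecError(
                f"v(t) range [{v.min():.3g}, {v.max():.3g}] leaves {list(V_BOUNDS)}"
            )

    # -- analytic ground truth ------------------------------------------------

    @property
    def omega(self) -> float:
        return 2.0 * np.pi / self.cycle_period

    def phase_tags(self) -> list[str]:
        return [f"P{10 * k:02d}" for k in range(self.n_phases)]

    def phase_times(self) -> np.ndarray:
        return np.arange(self.n_phases) * self.cycle_period / self.n_phases

    def breathing_fraction(self, t) -> np.ndarray:
        """Inflation fraction s(t) in [0, 1]; 1 at P00, 0 at P50."""
        return (1.0 + np.cos(self.omega * np.asarray(t, dtype=float))) / 2.0

    def elasticity_truth(self, t):
        """Ground-truth (E [kPa], v) at times t; first-order Fourier."""
        t = np.asarray(t, dtype=float)
        w = self.omega
        e0, e1, e2 = self.e_coeffs
        v0, v1, v2 = self.v_coeffs
        E = e0 + e1 * np.cos(w * t) + e2 * np.sin(w * t)
        v = v0 + v1 * np.cos(w * t) + v2 * np.sin(w * t)
        return E, v

    def _dilation(self) -> np.ndarray:
        """Per-axis dilation factors k*w such that prod(1 + k*w) = 1 + dV."""
        w = np.asarray(self.axis_weights, dtype=float)
        target = 1.0 + self.max_volume_change

        def f(k):
            return np.prod(1.0 + k * w) - target

        k = brentq(f, 0.0, 2.0)
        return k * w

    def _caudal_grading(self) -> float:
        """Grading strength q from the requested caudal displacement amplitude."""
        g = self._dilation()
        c3 = self.lung_semiaxes[2]
        if g[2] <= 0:
            return 0.0
        return self.displacement_amplitude / (g[2] * c3)

    def map_points(self, x: np.ndarray, s: float) -> np.ndarray:
        """Analytic motion map at inflation fraction s (truth for oracles)."""
        x = np.asarray(x, dtype=float)
        g = self._dilation()
        q = self._caudal_grading()
        c3 = self.lung_semiaxes[2]
        u = np.empty_like(x)
        u[..., 0] = s * g[0] * x[..., 0]
        u[..., 1] = s * g[1] * x[..., 1]
        u[..., 2] = s * g[2] * x[..., 2] * (1.0 - q * x[..., 2] / c3)
        return x + u

    def analytic_volume_ratio(self, s: float) -> float:
        """Continuum V(s)/V(0); the caudal grading integrates to zero."""
        return float(np.prod(1.0 + s * self._dilation()))


@dataclass
class PhaseBundle:
    """One phantom's full breathing cycle with ground truth attached."""

    spec: PhantomSpec
    reference_mesh: TetMesh                      # P50, undeformed
    phase_nodes: dict                            # tag -> (N, 3) true node positions
    displacements: dict                          # tag -> (K, 3) surface field vs P50
    surface_node_ids: np.ndarray
    times: np.ndarray
    truth_E: np.ndarray                          # kPa, per phase
    truth_v: np.ndarray
    mean_hu: np.ndarray = field(default=None)

    @property
    def n_phases(self) -> int:
        return self.spec.n_phases

    @property
    def phase_tags(self) -> list[str]:
        return self.spec.phase_tags()

    def mesh_for(self, tag: str) -> TetMesh:
        m = self.reference_mesh.with_nodes(self.phase_nodes[tag])
        return TetMesh(m.nodes, m.tets, m.region, m.surface_tris, phase_id=tag)

    def observed_tumor(self, tag: str) -> TetMesh:
        return self.mesh_for(tag).submesh(TUMOR)

    def surface_positions(self, tag: str) -> np.ndarray:
        """Observed (possibly noise-perturbed) surface node positions."""
        ref = self.reference_mesh.nodes[self.surface_node_ids]
        return ref + self.displacements[tag]

    def boundary_field(self, tag: str):
        from .fem import DisplacementField

        return DisplacementField(self.surface_node_ids, self.displacements[tag])

    def lung_volumes(self) -> np.ndarray:
        return np.array([self.mesh_for(tag).volume(LUNG) for tag in self.phase_tags])


def _ellipsoid_points(semiaxes, subdivisions: int) -> np.ndarray:
    sphere = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    return sphere.vertices * np.asarray(semiaxes, dtype=float)


def build_phantom_mesh(spec: PhantomSpec) -> TetMesh:
    """Tetrahedralize the ellipsoid lung with its embedded spherical tumor.

    Surface vertices come from subdivided icospheres (lung and tumor); the
    interior carries a cubic point lattice at ``mesh_edge_length`` spacing.
    Delaunay triangulation of the convex lung point set fills the volume
    exactly; tets are labeled tumor when their centroid falls inside the
    tumor sphere.  A tiny seeded jitter on lattice points avoids degenerate
    co-planar configurations.
    """
    rng = np.random.default_rng(spec.seed)
    a = np.asarray(spec.lung_semiaxes, dtype=float)
    c = np.asarray(spec.tumor_center, dtype=float)
    r = spec.tumor_radius
    h = spec.mesh_edge_length

    lung_surf = _ellipsoid_points(a, spec.lung_subdivisions)
    tumor_surf = c + _ellipsoid_points((r, r, r), spec.tumor_subdivisions)

    axes = [np.arange(-a[i] + h / 2, a[i], h) for i in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    grid = grid + rng.uniform(-0.05 * h, 0.05 * h, size=grid.shape)
    # keep lattice points clear of both surfaces
    rho = np.linalg.norm(grid / a, axis=1)
    d_tumor = np.linalg.norm(grid - c, axis=1)
    keep = (rho < 1.0 - 0.45 * h / a.min()) & (np.abs(d_tumor - r) > 0.45 * h)
    pts = np.vstack([lung_surf, tumor_surf, grid[keep], c])

    tets = Delaunay(pts).simplices
    centroids = pts[tets].mean(axis=1)
    region = np.where(
        np.linalg.norm(centroids - c, axis=1) < r, TUMOR, LUNG
    ).astype(object)
    mesh = TetMesh(nodes=pts, tets=tets, region=region)
    mesh.validate()
    if not (region == TUMOR).any():
        raise MeshValidationError("tumor region empty; refine the mesh")
    return mesh


def generate_phantom(spec: PhantomSpec) -> PhaseBundle:
    """Build the phantom mesh and carry it through the breathing cycle.

    Deterministic for a fixed seed.  Per-phase displacement fields are the
    analytic map restricted to lung-surface nodes, relative to the P50
    reference; optional Gaussian noise (``noise_sigma``, mm) emulates
    registration error on every phase except the reference.
    """
    mesh = build_phantom_mesh(spec)
    rng = np.random.default_rng(spec.seed + 1)
    tags = spec.phase_tags()
    times = spec.phase_times()
    fracs = spec.breathing_fraction(times)
    surf = mesh.surface_nodes()
    ref = mesh.nodes

    phase_nodes, displacements = {}, {}
    for tag, s in zip(tags, fracs):
        pos = spec.map_points(ref, float(s))
        phase_nodes[tag] = pos
        du = (pos - ref)[surf]
        if spec.noise_sigma > 0 and tag != "P50":
            du = du + rng.normal(0.0, spec.noise_sigma, size=du.shape)
        displacements[tag] = du
    # the reference phase is exact by construction
    displacements["P50"] = np.zeros((len(surf), 3))
    phase_nodes["P50"] = ref.copy()

    E, v = spec.elasticity_truth(times)
    bundle = PhaseBundle(
        spec=spec,
        reference_mesh=TetMesh(mesh.nodes, mesh.tets, mesh.region,
                               mesh.surface_tris, phase_id="P50"),
        phase_nodes=phase_nodes,
        displacements=displacements,
        surface_node_ids=surf,
        times=times,
        truth_E=E,
        truth_v=v,
    )
    bundle.mean_hu = emulate_hu(bundle)
    return bundle


def emulate_hu(bundle: PhaseBundle, mass_fraction: float | None = None) -> np.ndarray:
    """Per-phase mean lung CT number from an air-fraction model.

    HU(V) = -1000 * (1 - m * V50 / V): tissue mass is conserved while air
    content scales with volume, so mean HU falls monotonically as the lung
    inflates.  m is the tissue fraction at the reference volume.
    """
    m = bundle.spec.hu_mass_fraction if mass_fraction is None else mass_fraction
    vols = bundle.lung_volumes()
    v50 = vols[bundle.phase_tags.index("P50")]
    hu = -1000.0 * (1.0 - m * v50 / vols)
    return np.clip(hu, -1000.0, 0.0)


# -- bundle persistence ------------------------------------------------------


def write_bundle(bundle: PhaseBundle, outdir) -> None:
    """Write one MSH per phase, one displacement CSV per phase, and a JSON
    manifest carrying times, elasticity truth and the generating spec."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for tag in bundle.phase_tags:
        mio.write_mesh(bundle.mesh_for(tag), outdir / f"phase_{tag}.msh")
        mio.write_displacement_csv(
            outdir / f"displacement_{tag}.csv",
            bundle.surface_node_ids,
            bundle.displacements[tag],
        )
    manifest = {
        "spec": asdict(bundle.spec),
        "phase_tags": bundle.phase_tags,
        "times_s": bundle.times.tolist(),
        "truth_E_kPa": bundle.truth_E.tolist(),
        "truth_v": bundle.truth_v.tolist(),
        "mean_hu": bundle.mean_hu.tolist() if bundle.mean_hu is not None else None,
        "seed": bundle.spec.seed,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def read_bundle(indir) -> PhaseBundle:
    indir = Path(indir)
    manifest = json.loads((indir / "manifest.json").read_text())
    spec_dict = manifest["spec"]
    for key in ("lung_semiaxes", "tumor_center", "e_coeffs", "v_coeffs",
                "axis_weights"):
        spec_dict[key] = tuple(spec_dict[key])
    spec = PhantomSpec(**spec_dict)
    tags = manifest["phase_tags"]
    ref = mio.read_mesh(indir / "phase_P50.msh")
    phase_nodes, displacements = {}, {}
    surf_ids = None
    for tag in tags:
        m = mio.read_mesh(indir / f"phase_{tag}.msh")
        phase_nodes[tag] = m.nodes
        ids, du = mio.read_displacement_csv(indir / f"displacement_{tag}.csv")
        displacements[tag] = du
        surf_ids = ids
    bundle = PhaseBundle(
        spec=spec,
        reference_mesh=ref,
        phase_nodes=phase_nodes,
        displacements=displacements,
        surface_node_ids=surf_ids,
        times=np.asarray(manifest["times_s"]),
        truth_E=np.asarray(manifest["truth_E_kPa"]),
        truth_v=np.asarray(manifest["truth_v"]),
        mean_hu=np.asarray(manifest["mean_hu"]) if manifest["mean_hu"] else None,
    )
    return bundle


# -- synthetic cohorts -------------------------------------------------------


def amplitude_graded_cohort(n_cases: int, seed: int, **spec_overrides):
    """Phantom specs with monotonically graded diaphragm amplitude.

    Used for the traction-vs-motion correlation study: larger caudal drive
    produces both larger tumor motion and larger surface traction.  Small
    seeded perturbations of the other parameters decorrelate the cohort.
    """
    rng = np.random.default_rng(seed)
    amplitudes = np.linspace(2.0, 14.0, n_cases)
    specs = []
    for i, amp in enumerate(amplitudes):
        dv = float(np.clip(0.13 + rng.normal(0, 0.02), 0.05, 0.39))
        specs.append(
            PhantomSpec(
                displacement_amplitude=float(amp),
                max_volume_change=dv,
                seed=int(seed + 1000 + i),
                **spec_overrides,
            )
        )
    return specs


def synthetic_feature_cohort(
    n_cases: int,
    seed: int,
    age_effect_E: float = -0.5,
    age_effect_v: float = 0.2,
    noise_sigma: float = 0.05,
    n_features: int = 11,
    age_index: int = 6,
):
    """Feature matrix and elasticity targets with a single true age effect.

    All features are standardized independent draws except the age column,
    which alone carries signal: avg E falls with age, avg v rises, plus
    Gaussian noise of ``noise_sigma`` (standardized-target units).  Mirrors
    the clinical finding that aging lung softens and becomes less
    compressible, as an identifiable test bed for the two-step LASSO.
    """
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n_cases, n_features))
    age = X[:, age_index]
    avg_E = 6.5 + age_effect_E * age + rng.normal(0, noise_sigma, n_cases)
    avg_v = 0.30 + age_effect_v * 0.05 * age + rng.normal(0, noise_sigma * 0.05, n_cases)
    return X, avg_E, avg_v
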