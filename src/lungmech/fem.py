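"""Quasi-static hyperelastic finite-element solver.

Linear 4-node tetrahedra with single-point quadrature; total strain energy
is minimized by Newton-Raphson with an analytic tangent, backtracking line
search, and displacement-increment continuation.  Surface displacements act
as Dirichlet boundary conditions: the lung surface is prescribed, interior
lung and tumor nodes equilibrate.  No body forces (quasi-static breathing,
supine gravity not modeled).

Linear tets with one-point quadrature are known to lock volumetrically as
v -> 0.5; results are validated for v <= 0.45, comfortably covering the
physiological search box v in [0.1, 0.49] away from its upper corner.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .materials import Material, material_tangent, pk1_stress, strain_energy
from .mesh import TetMesh, tet_signed_volumes


class SolverError(RuntimeError):
    """Newton iteration failed to converge; carries the residual history."""

    def __init__(self, message: str, residual_history=None, phase=None):
        super().__init__(message)
        self.residual_history = residual_history or []
        self.phase = phase


@dataclass
class DisplacementField:
    """Prescribed displacements (mm) on a set of nodes."""

    node_ids: np.ndarray
    u: np.ndarray

    def __post_init__(self) -> None:
        self.node_ids = np.asarray(self.node_ids, dtype=np.int64)
        self.u = np.asarray(self.u, dtype=float)
        if self.u.shape != (len(self.node_ids), 3):
            raise ValueError("displacement field must be (K, 3) over K node ids")


@dataclass
class SolverConfig:
    """Newton/continuation settings.

    tol is relative: convergence when the residual norm falls below
    ``tol * max(reference force scale, abs_floor)``.
    """

    tol: float = 1e-10
    abs_tol: float = 1e-12
    max_newton_iters: int = 30
    n_increments: int = 5
    line_search: bool = True
    max_line_search: int = 12
    quadrature: str = "1pt"


@dataclass
class FEMSolution:
    """Converged equilibrium state of one transition."""

    u: np.ndarray                  # (N, 3) nodal displacements, mm
    F: np.ndarray                  # (M, 3, 3) per-element deformation gradient
    P: np.ndarray                  # (M, 3, 3) per-element PK1 stress, Pa
    W: np.ndarray                  # (M,) per-element energy density, Pa
    newton_iterations: int
    residual_norm: float
    converged: bool
    mesh: TetMesh | None = None
    lung_mat: Material | None = None
    tumor_mat: Material | None = None

    def deformed_mesh(self) -> TetMesh:
        return self.mesh.with_nodes(self.mesh.nodes + self.u)

    @property
    def tumor_centroid_displacement(self) -> np.ndarray:
        before = self.mesh.centroid("tumor")
        after = self.deformed_mesh().centroid("tumor")
        return after - before


class _Assembler:
    """Precomputed reference-configuration quantities for one mesh."""

    def __init__(self, mesh: TetMesh, lung_mat: Material, tumor_mat: Material):
        self.mesh = mesh
        self.lung_mat = lung_mat
        self.tumor_mat = tumor_mat
        nodes, tets = mesh.nodes, mesh.tets
        self.vols = tet_signed_volumes(nodes, tets)
        edges = nodes[tets[:, 1:]] - nodes[tets[:, :1]]        # (M, 3, 3) rows
        Dinv = np.linalg.inv(np.swapaxes(edges, 1, 2))          # D columns=edges
        grads = np.empty((len(tets), 4, 3))
        grads[:, 1:, :] = Dinv                                  # rows of D^-1
        grads[:, 0, :] = -Dinv.sum(axis=1)
        self.grads = grads
        self.lung_els = np.flatnonzero(mesh.region == "lung")
        self.tumor_els = np.flatnonzero(mesh.region == "tumor")
        # sparse triplet pattern for the 12x12 element blocks
        dof = (3 * tets[:, :, None] + np.arange(3)[None, None, :]).reshape(-1, 12)
        self.rows = np.repeat(dof, 12, axis=1).ravel()
        self.cols = np.tile(dof, (1, 12)).ravel()
        self.ndof = 3 * len(nodes)

    def deformation_gradients(self, u: np.ndarray) -> np.ndarray:
        U = u[self.mesh.tets]                                   # (M, 4, 3)
        return np.eye(3) + np.einsum("mai,maJ->miJ", U, self.grads)

    def _per_region(self, F, fn):
        out = None
        for els, mat in ((self.lung_els, self.lung_mat), (self.tumor_els, self.tumor_mat)):
            if len(els) == 0:
                continue
            val = fn(F[els], mat)
            if out is None:
                out = np.zeros((len(F),) + np.shape(val)[1:])
            out[els] = val
        return out

    def energy(self, u: np.ndarray) -> float:
        F = self.deformation_gradients(u)
        W = self._per_region(F, strain_energy)
        return float(np.dot(self.vols, W))

    def stress_and_energy(self, F):
        P = self._per_region(F, pk1_stress)
        W = self._per_region(F, strain_energy)
        return P, W

    def internal_forces(self, P: np.ndarray) -> np.ndarray:
        f = np.einsum("m,miJ,maJ->mai", self.vols, P, self.grads)
        out = np.zeros((len(self.mesh.nodes), 3))
        np.add.at(out, self.mesh.tets, f)
        return out

    def stiffness(self, F: np.ndarray) -> sp.csr_matrix:
        A = self._per_region(F, material_tangent)               # (M,3,3,3,3)
        Ke = np.einsum("m,miJkL,maJ,mbL->maibk", self.vols, A, self.grads, self.grads)
        data = Ke.reshape(len(F), 12, 12).ravel()
        K = sp.coo_matrix((data, (self.rows, self.cols)), shape=(self.ndof, self.ndof))
        return K.tocsr()


def solve_displacement(
    mesh: TetMesh,
    lung_mat: Material,
    tumor_mat: Material,
    boundary: DisplacementField,
    solver_cfg: SolverConfig | None = None,
) -> FEMSolution:
    """Equilibrate the lung-tumor system under prescribed surface motion.

    ``boundary`` must cover every lung-surface node; interior lung and all
    tumor nodes are free.  The prescribed displacement is applied in
    ``n_increments`` continuation steps, each solved by Newton-Raphson on
    the total-strain-energy gradient with an analytic stiffness.
    """
    cfg = solver_cfg or SolverConfig()
    surf = mesh.surface_nodes()
    missing = np.setdiff1d(surf, boundary.node_ids)
    if len(missing):
        raise ValueError(
            f"boundary field must cover all {len(surf)} surface nodes; "
            f"{len(missing)} missing, first few {missing[:5].tolist()}"
        )
    asm = _Assembler(mesh, lung_mat, tumor_mat)
    n = len(mesh.nodes)
    fixed = np.zeros(n, dtype=bool)
    fixed[boundary.node_ids] = True
    free = np.flatnonzero(~fixed)
    free_dofs = (3 * free[:, None] + np.arange(3)).ravel()

    u_bc_full = np.zeros((n, 3))
    u_bc_full[boundary.node_ids] = boundary.u

    u = np.zeros((n, 3))
    history: list[float] = []
    total_iters = 0
    res_norm = 0.0
    bc_scale = max(float(np.abs(boundary.u).max()), 1.0)

    for inc in range(1, cfg.n_increments + 1):
        frac = inc / cfg.n_increments
        u[fixed] = frac * u_bc_full[fixed]
        if len(free) == 0:
            continue
        ref_scale = None
        for it in range(cfg.max_newton_iters):
            F = asm.deformation_gradients(u)
            P, _ = asm.stress_and_energy(F)
            f_int = asm.internal_forces(P)
            r = f_int.ravel()[free_dofs]
            res_norm = float(np.linalg.norm(r))
            history.append(res_norm)
            if ref_scale is None:
                # force scale: stiffness * characteristic displacement
                K = asm.stiffness(F)
                Kff = K[free_dofs][:, free_dofs]
                diag = np.abs(Kff.diagonal())
                ref_scale = max(float(diag.max()) * bc_scale, cfg.abs_tol)
            else:
                K = None
            if res_norm <= max(cfg.tol * ref_scale, cfg.abs_tol):
                break
            if K is None:
                K = asm.stiffness(F)
                Kff = K[free_dofs][:, free_dofs]
            du = spla.spsolve(Kff.tocsc(), -r)
            step = 1.0
            if cfg.line_search:
                e0 = asm.energy(u)
                slope = float(r @ du)
                for _ in range(cfg.max_line_search):
                    u_try = u.copy()
                    u_try.ravel()[free_dofs] += step * du
                    try:
                        e1 = asm.energy(u_try)
                    except Exception:
                        e1 = np.inf
                    if e1 <= e0 + 1e-4 * step * slope or not np.isfinite(e0):
                        break
                    step *= 0.5
            u.ravel()[free_dofs] += step * du
            total_iters += 1
        else:
            raise SolverError(
                f"Newton failed to converge at increment {inc}/{cfg.n_increments}: "
                f"residual {res_norm:.3e}",
                residual_history=history,
            )

    F = asm.deformation_gradients(u)
    P, W = asm.stress_and_energy(F)
    return FEMSolution(
        u=u, F=F, P=P, W=W,
        newton_iterations=total_iters,
        residual_norm=res_norm,
        converged=True,
        mesh=mesh, lung_mat=lung_mat, tumor_mat=tumor_mat,
    )


def phase_cycle_order(n_phases: int = 10, start_index: int = 5) -> list[str]:
    """Phase tags in propagation order P50 -> P60 -> ... -> P40 -> P50."""
    tags = [f"P{10 * ((start_index + k) % n_phases):02d}" for k in range(n_phases)]
    return tags + [tags[0]]


def propagate_cycle(bundle, lung_materials, tumor_mat: Material,
                    solver_cfg: SolverConfig | None = None,
                    reference: str = "observed"):
    """Propagate the tumor through the full breathing cycle.

    Transitions follow the order P50 -> P60 -> ... -> P40 -> P50.  Two
    reference schemes are supported:

    * ``"observed"`` (default): each transition Pi -> Pj is solved on the
      bundle's observed phase-Pi mesh (per-phase remeshing: the lung
      geometry is re-anchored to observation at every phase) and the
      converged displacement is applied to the propagated tumor nodes.
    * ``"accumulated"``: fully self-contained simulation — the converged
      field updates the whole simulated mesh, which becomes the next
      transition's reference.  This accrues re-referencing hysteresis and
      is kept for sensitivity studies.

    Parameters
    ----------
    bundle : PhaseBundle from :mod:`lungmech.phantom` (or any object with
        ``reference_mesh``, ``mesh_for``, ``surface_node_ids`` and
        ``surface_positions(tag)``).
    lung_materials : one Material per transition (len = n_phases), or a
        single Material used for every transition.
    tumor_mat : tumor inclusion material.

    Returns
    -------
    (solutions, tumor_meshes, order) : per-transition FEM solutions, the
    propagated tumor submesh after each transition, and the phase order.
    """
    if reference not in ("observed", "accumulated"):
        raise ValueError(f"unknown reference scheme {reference!r}")
    order = phase_cycle_order(bundle.n_phases)
    if isinstance(lung_materials, Material):
        lung_materials = [lung_materials] * bundle.n_phases
    if len(lung_materials) != bundle.n_phases:
        raise ValueError("need one lung material per transition")

    mesh = bundle.reference_mesh
    surf_ids = bundle.surface_node_ids
    tumor_node_ids = np.unique(mesh.tets[mesh.region == "tumor"])
    tumor_template = mesh.submesh("tumor")
    tumor_pos = mesh.nodes[tumor_node_ids].copy()
    current = mesh.nodes.copy()
    solutions, tumor_meshes = [], []
    for k, tag in enumerate(order[1:]):
        if reference == "observed":
            step_mesh = bundle.mesh_for(order[k])
        else:
            step_mesh = mesh.with_nodes(current)
        target = bundle.surface_positions(tag)
        bc = DisplacementField(surf_ids, target - step_mesh.nodes[surf_ids])
        try:
            sol = solve_displacement(step_mesh, lung_materials[k], tumor_mat,
                                     bc, solver_cfg)
        except SolverError as err:
            err.phase = tag
            raise
        current = step_mesh.nodes + sol.u
        tumor_pos = tumor_pos + sol.u[tumor_node_ids]
        solutions.append(sol)
        tumor_meshes.append(tumor_template.with_nodes(tumor_pos))
    return solutions, tumor_meshes, order
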