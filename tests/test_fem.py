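"""Hyperelastic solver: exact modes, patch test, phantom oracles, cycling."""

import numpy as np
import pytest

from conftest import FAST_SOLVER
from lungmech.fem import (
    DisplacementField,
    SolverConfig,
    phase_cycle_order,
    propagate_cycle,
    solve_displacement,
)
from lungmech.materials import NH, SVK, Material, tumor_material
from lungmech.phantom import PhantomSpec, PhaseBundle, generate_phantom


def surface_field(mesh, fn):
    ids = mesh.surface_nodes()
    return DisplacementField(ids, fn(mesh.nodes[ids]))


class TestSolve:
    def test_rigid_translation_is_a_zero_energy_mode(self, default_bundle, lung_material):
        m = default_bundle.reference_mesh
        t = np.array([3.0, 4.0, 0.0])
        sol = solve_displacement(m, lung_material, tumor_material(),
                                 surface_field(m, lambda x: np.tile(t, (len(x), 1))),
                                 FAST_SOLVER)
        np.testing.assert_allclose(sol.u, np.tile(t, (len(sol.u), 1)), atol=1e-9)
        # stress is numerically zero: ~1e-5 Pa round-off against the 49 MPa
        # tumor stiffness, vs a physical signal scale of ~1e2-1e3 Pa
        assert np.abs(sol.P).max() < 1e-4

    @pytest.mark.parametrize("model", [SVK, NH])
    def test_patch_test_affine_field(self, default_bundle, model):
        # homogeneous material: affine Dirichlet data must be reproduced
        # exactly at interior nodes with constant element stress
        m = default_bundle.reference_mesh
        mat = Material(model, 5000.0, 0.35)
        A = np.diag([1.02, 1.0, 1.0])
        sol = solve_displacement(m, mat, mat,
                                 surface_field(m, lambda x: x @ (A - np.eye(3)).T),
                                 FAST_SOLVER)
        expected = m.nodes @ (A - np.eye(3)).T
        assert np.abs(sol.u - expected).max() < 1e-8
        np.testing.assert_allclose(
            sol.F, np.broadcast_to(A, sol.F.shape), atol=1e-6 * np.abs(A).max()
        )
        P_mean = sol.P.mean(axis=0)
        assert np.abs(sol.P - P_mean).max() <= 1e-6 * max(np.abs(P_mean).max(), 1.0)

    def test_boundary_must_cover_surface(self, default_bundle, lung_material):
        m = default_bundle.reference_mesh
        ids = m.surface_nodes()[:-3]
        with pytest.raises(ValueError, match="cover"):
            solve_displacement(m, lung_material, tumor_material(),
                               DisplacementField(ids, np.zeros((len(ids), 3))),
                               FAST_SOLVER)

    def test_affine_phantom_matches_analytic_map(self, affine_bundle, lung_material):
        # amplitude-0 phantom: the motion map is affine, hence an exact
        # equilibrium; the FEM tumor centroid must track the analytic map
        sol = solve_displacement(affine_bundle.mesh_for("P50"), lung_material,
                                 tumor_material(),
                                 affine_bundle.boundary_field("P00"),
                                 FAST_SOLVER)
        sim = sol.deformed_mesh().centroid("tumor")
        truth = affine_bundle.observed_tumor("P00").centroid()
        assert np.linalg.norm(sim - truth) < 0.2

    def test_solution_metadata(self, p00_solution):
        assert p00_solution.converged
        assert p00_solution.newton_iterations > 0
        assert np.all(np.linalg.det(p00_solution.F) > 0)


class TestCycle:
    def test_phase_order(self):
        order = phase_cycle_order(10)
        assert order[0] == order[-1] == "P50"
        assert order[1:6] == ["P60", "P70", "P80", "P90", "P00"]
        assert len(order) == 11

    def test_zero_displacement_bundle_is_stationary(self, default_bundle, lung_material):
        b = default_bundle
        ref = b.reference_mesh
        zero = {tag: np.zeros_like(b.displacements[tag]) for tag in b.phase_tags}
        frozen = PhaseBundle(
            spec=b.spec, reference_mesh=ref,
            phase_nodes={tag: ref.nodes for tag in b.phase_tags},
            displacements=zero, surface_node_ids=b.surface_node_ids,
            times=b.times, truth_E=b.truth_E, truth_v=b.truth_v,
            mean_hu=b.mean_hu,
        )
        _, tumors, _ = propagate_cycle(frozen, lung_material, tumor_material(),
                                       FAST_SOLVER)
        start = ref.submesh("tumor")
        for tm in tumors:
            np.testing.assert_allclose(tm.nodes, start.nodes, atol=1e-9)

    def test_cycle_returns_tumor_to_start(self, default_bundle, lung_material):
        _, tumors, _ = propagate_cycle(default_bundle, lung_material,
                                       tumor_material(), FAST_SOLVER)
        start = default_bundle.reference_mesh.centroid("tumor")
        err = np.linalg.norm(tumors[-1].centroid() - start)
        assert err < 0.1

    def test_trajectory_tracks_analytic_map_on_affine_phantom(
        self, affine_bundle, lung_material
    ):
        _, tumors, order = propagate_cycle(affine_bundle, lung_material,
                                           tumor_material(), FAST_SOLVER)
        errs = []
        for k, tag in enumerate(order[1:]):
            truth = affine_bundle.observed_tumor(tag).centroid()
            errs.append(np.linalg.norm(tumors[k].centroid() - truth))
        assert max(errs) < 0.5

    def test_trajectory_correlates_on_graded_phantom(self, default_bundle, lung_material):
        _, tumors, order = propagate_cycle(default_bundle, lung_material,
                                           tumor_material(), FAST_SOLVER)
        sim_z = [tm.centroid()[2] for tm in tumors]
        true_z = [default_bundle.observed_tumor(tag).centroid()[2]
                  for tag in order[1:]]
        assert np.corrcoef(sim_z, true_z)[0, 1] > 0.99

    def test_material_count_validated(self, default_bundle, lung_material):
        with pytest.raises(ValueError, match="per transition"):
            propagate_cycle(default_bundle, [lung_material] * 3, tumor_material())


class TestMeshConvergence:
    def test_tumor_displacement_stable_under_refinement(self, lung_material):
        from lungmech.mesh import mesh_convergence_report

        bundles = {h: generate_phantom(PhantomSpec(mesh_edge_length=h))
                   for h in (20.0, 16.0, 12.0)}

        def boundary(mesh):
            b = next(bb for bb in bundles.values()
                     if bb.reference_mesh is mesh)
            return b.boundary_field("P00")

        def solve(mesh, bc):
            return solve_displacement(mesh, lung_material, tumor_material(),
                                      bc, FAST_SOLVER)

        report = mesh_convergence_report(
            [b.reference_mesh for b in bundles.values()], boundary, solve
        )
        assert len(report) == 3
        assert report[0]["n_tets"] < report[-1]["n_tets"]
        # medium -> fine change below 5%
        assert report[-1]["rel_change"] < 0.05
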