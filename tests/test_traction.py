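"""Surface traction fields: constitutive identity, equilibrium, directions."""

import numpy as np
import pytest
import trimesh
from scipy.spatial.transform import Rotation

from conftest import FAST_SOLVER
from lungmech.fem import DisplacementField, solve_displacement
from lungmech.io import tetrahedralize_surface
from lungmech.materials import Material, tumor_material
from lungmech.traction import (
    correlate_traction_motion,
    directional_summary,
    traction_field,
)


@pytest.fixture(scope="module")
def ball_mesh():
    sph = trimesh.creation.icosphere(subdivisions=2, radius=20.0)
    return tetrahedralize_surface(sph, target_edge_length=7.0)


@pytest.fixture(scope="module")
def expanded_ball_solution(ball_mesh):
    """Uniform 5% isotropic expansion of a homogeneous ball."""
    mat = Material("NH", 5000.0, 0.3)
    ids = ball_mesh.surface_nodes()
    bc = DisplacementField(ids, 0.05 * ball_mesh.nodes[ids])
    return solve_displacement(ball_mesh, mat, mat, bc, FAST_SOLVER)


class TestTractionField:
    def test_constitutive_identity_t_equals_p_n0(self, p00_solution):
        tf = traction_field(p00_solution)
        from lungmech.traction import _face_to_tet

        owners = _face_to_tet(p00_solution.mesh)
        expected = np.einsum("kij,kj->ki", p00_solution.P[owners], tf.n0)
        np.testing.assert_array_equal(tf.T, expected)

    def test_cauchy_stress_symmetric(self, p00_solution):
        tf = traction_field(p00_solution)
        asym = np.abs(tf.sigma - np.swapaxes(tf.sigma, 1, 2)).max()
        assert asym <= 1e-8 * np.abs(tf.sigma).max()

    def test_rigid_translation_zero_traction(self, default_bundle, lung_material):
        m = default_bundle.reference_mesh
        ids = m.surface_nodes()
        sol = solve_displacement(m, lung_material, tumor_material(),
                                 DisplacementField(ids, np.tile([3.0, 4.0, 0.0],
                                                                (len(ids), 1))),
                                 FAST_SOLVER)
        tf = traction_field(sol)
        assert tf.magnitude.max() < 1e-6  # Pa
        assert np.abs(tf.T_consistent).max() < 1e-6

    def test_uniform_expansion_traction_parallel_to_normal(self, expanded_ball_solution):
        tf = traction_field(expanded_ball_solution)
        assert tf.theta.max() < 5.0
        assert tf.magnitude.min() > 0.0

    def test_global_equilibrium_consistent_flux(self, p00_solution,
                                                expanded_ball_solution):
        for sol in (p00_solution, expanded_ball_solution):
            tf = traction_field(sol)
            assert tf.equilibrium_residual() < 1e-3
            # face-stress variant carries the O(h) consistency error
            assert tf.equilibrium_residual("face") < 0.5

    def test_unconverged_solution_rejected(self, p00_solution):
        import dataclasses

        bad = dataclasses.replace(p00_solution, converged=False)
        with pytest.raises(ValueError, match="converged"):
            traction_field(bad)

    def test_theta_invariant_under_global_rotation(self, ball_mesh):
        mat = Material("NH", 4000.0, 0.3)
        ids = ball_mesh.surface_nodes()
        rng = np.random.default_rng(2)
        A = np.eye(3) + 0.03 * rng.standard_normal((3, 3))
        bc = DisplacementField(ids, ball_mesh.nodes[ids] @ (A - np.eye(3)).T)
        sol = solve_displacement(ball_mesh, mat, mat, bc, FAST_SOLVER)
        theta = traction_field(sol).theta

        R = Rotation.from_euler("zyx", [30, -20, 45], degrees=True).as_matrix()
        rotated = ball_mesh.with_nodes(ball_mesh.nodes @ R.T)
        A_rot = R @ A @ R.T
        bc_rot = DisplacementField(ids, rotated.nodes[ids] @ (A_rot - np.eye(3)).T)
        sol_rot = solve_displacement(rotated, mat, mat, bc_rot, FAST_SOLVER)
        theta_rot = traction_field(sol_rot).theta
        np.testing.assert_allclose(theta_rot, theta, atol=1e-6)


class TestDirectionalSummary:
    def _centroids(self, g50, g_true, g_sim):
        return {"G50": np.asarray(g50), "G00_true": np.asarray(g_true),
                "G00_sim": np.asarray(g_sim)}

    def test_isotropic_expansion_all_directions_equal(self, ball_mesh,
                                                      expanded_ball_solution):
        tf = traction_field(expanded_ball_solution)
        s = directional_summary(
            tf, self._centroids([0, 0, 0], [0, 0, 15], [10, 0, 0]), ball_mesh
        )
        assert s.t.amplitude == pytest.approx(s.s.amplitude, rel=0.05)
        assert s.t.amplitude == pytest.approx(s.l.amplitude, rel=0.05)

    def test_true_equals_sim_when_centroids_agree(self, p00_solution, default_bundle):
        tf = traction_field(p00_solution)
        g50 = default_bundle.reference_mesh.centroid("tumor")
        g00 = g50 + np.array([0.0, 0.0, -5.0])
        s = directional_summary(tf, self._centroids(g50, g00, g00),
                                default_bundle.reference_mesh)
        assert s.t.amplitude == s.s.amplitude
        assert s.t.angle == s.s.angle

    def test_zero_direction_rejected(self, p00_solution, default_bundle):
        tf = traction_field(p00_solution)
        g50 = default_bundle.reference_mesh.centroid("tumor")
        with pytest.raises(ValueError, match="zero-length"):
            directional_summary(tf, self._centroids(g50, g50, g50 + [0, 0, 1]),
                                default_bundle.reference_mesh)

    def test_empty_cone_falls_back_to_best_aligned_face(self, p00_solution,
                                                        default_bundle):
        tf = traction_field(p00_solution)
        g50 = default_bundle.reference_mesh.centroid("tumor")
        g00 = g50 + np.array([0.0, 0.0, -5.0])
        s = directional_summary(tf, self._centroids(g50, g00, g00),
                                default_bundle.reference_mesh, cone_deg=0.01)
        assert 1 <= s.t.n_faces <= 2  # ties allowed on symmetric meshes
        assert s.t.amplitude > 0.0


class TestCorrelation:
    def test_exact_linear_relation(self):
        class S:
            def __init__(self, x):
                self.x = x

            def as_dict(self):
                return {"amplitude_t": 2 * self.x, "angle_t": 90 - self.x}

        xs = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        table = correlate_traction_motion([S(x) for x in xs], xs)
        amp = table[(table.direction == "t") & (table.quantity == "amplitude")]
        ang = table[(table.direction == "t") & (table.quantity == "angle")]
        assert amp.pearson_r.iloc[0] == pytest.approx(1.0)
        assert amp.r_squared.iloc[0] == pytest.approx(1.0)
        assert ang.pearson_r.iloc[0] == pytest.approx(-1.0)

    def test_minimum_cases_and_variance_guards(self):
        class S:
            def as_dict(self):
                return {"amplitude_t": 1.0}

        with pytest.raises(ValueError, match="3 paired"):
            correlate_traction_motion([S(), S()], [1.0, 2.0])
        with pytest.raises(ValueError, match="zero variance"):
            correlate_traction_motion([S(), S(), S()], [1.0, 2.0, 3.0])

    def test_permutation_null_matches_exact_distribution(self):
        # shuffled pairings destroy the correlation; the empirical null
        # matches the exact null law r^2 ~ Beta(1/2, (n-2)/2) for n = 15
        from scipy import stats

        rng = np.random.default_rng(10)
        n = 15
        x = np.linspace(1, 10, n)
        y = 2 * x + rng.normal(0, 0.5, n)
        null_ok = sum(
            abs(np.corrcoef(x, rng.permutation(y))[0, 1]) <= 0.5
            for _ in range(1000)
        ) / 1000.0
        exact = stats.beta(0.5, (n - 2) / 2.0).cdf(0.25)
        assert null_ok == pytest.approx(exact, abs=0.03)
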