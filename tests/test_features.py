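"""Feature extraction and the two-step LASSO with LOOCV."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from conftest import FAST_SOLVER
from lungmech.features import (
    FEATURE_NAMES,
    LassoLoocvRegressor,
    adi,
    extract_features,
    features_frame,
    lasso_loocv,
    principal_strains,
    sri,
    volume_averaged_F,
)
from lungmech.fem import solve_displacement
from lungmech.materials import Material, tumor_material
from lungmech.phantom import PhantomSpec, PhaseBundle, generate_phantom, \
    synthetic_feature_cohort


class TestPrincipalStrains:
    def test_identity(self):
        assert principal_strains(np.eye(3)) == (1.0, 1.0, 1.0)

    def test_diagonal_gradient(self):
        l = principal_strains(np.diag([1.2, 1.1, 1.0]))
        np.testing.assert_allclose(l, (1.2, 1.1, 1.0), atol=1e-12)

    def test_rotation_invariance(self):
        R = Rotation.from_euler("xyz", [15, 40, -70], degrees=True).as_matrix()
        l = principal_strains(R @ np.diag([1.2, 1.1, 1.0]))
        np.testing.assert_allclose(l, (1.2, 1.1, 1.0), atol=1e-10)

    def test_negative_determinant_rejected(self):
        with pytest.raises(ValueError):
            principal_strains(np.diag([-1.0, 1.0, 1.0]))


class TestShapeIndices:
    def test_adi_hand_value(self):
        assert adi(1.2, 1.1, 1.0) == pytest.approx(0.13514, abs=1e-4)

    def test_adi_isotropic_zero_and_scale_invariant(self):
        assert adi(1.3, 1.3, 1.3) == 0.0
        assert adi(2.4, 2.2, 2.0) == pytest.approx(adi(1.2, 1.1, 1.0), rel=1e-12)

    def test_sri_hand_value(self):
        # (2/pi) * arctan sqrt(l3 (l1-l2) / (l2 (l2-l3)))
        expected = (2 / np.pi) * np.arctan(np.sqrt(1.0 * 0.1 / (1.1 * 0.1)))
        assert expected == pytest.approx(0.48484, abs=1e-4)
        assert sri(1.2, 1.1, 1.0) == pytest.approx(expected, abs=1e-12)

    def test_sri_degenerate_conventions(self):
        assert sri(1.2, 1.2, 1.0) == 0.0   # oblate limit (l1 = l2)
        assert sri(1.2, 1.0, 1.0) == 1.0   # prolate limit (l2 = l3)
        assert sri(1.0, 1.0, 1.0) == 0.0   # isotropic

    def test_sri_range(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            l = np.sort(rng.uniform(0.8, 1.5, 3))[::-1]
            assert 0.0 <= sri(*l) <= 1.0

    def test_ordering_enforced(self):
        with pytest.raises(ValueError):
            sri(1.0, 1.1, 1.2)


def _static_bundle(bundle):
    """Copy of a bundle where every phase equals the reference."""
    ref = bundle.reference_mesh
    return PhaseBundle(
        spec=bundle.spec, reference_mesh=ref,
        phase_nodes={tag: ref.nodes for tag in bundle.phase_tags},
        displacements={tag: np.zeros_like(bundle.displacements[tag])
                       for tag in bundle.phase_tags},
        surface_node_ids=bundle.surface_node_ids,
        times=bundle.times, truth_E=bundle.truth_E, truth_v=bundle.truth_v,
        mean_hu=np.full(bundle.n_phases, -800.0),
    )


class TestExtractFeatures:
    def test_static_bundle_yields_zero_changes(self, default_bundle, lung_material):
        frozen = _static_bundle(default_bundle)
        sol = solve_displacement(frozen.mesh_for("P50"), lung_material,
                                 tumor_material(), frozen.boundary_field("P00"),
                                 FAST_SOLVER)
        f = extract_features(frozen, {"age": 64, "bmi": 21.8}, sol)
        for name in ("dV", "dHU", "dx", "dy", "dz", "dSV", "LMA", "ADI"):
            assert getattr(f, name) == pytest.approx(0.0, abs=1e-6), name
        assert f.Age == 64 and f.BMI == 21.8

    def test_engineered_volume_change_recovered(self, default_bundle, p00_solution):
        f = extract_features(default_bundle, {"age": 64, "bmi": 21.8},
                             p00_solution)
        assert f.dV == pytest.approx(0.13, rel=0.01)
        assert f.LMA > 0.0
        assert f.dHU > 0.0  # mean HU falls on inhale; ratio of negatives > 0

    def test_isotropic_scaling_bounding_box_and_sv(self, affine_bundle,
                                                   lung_material):
        # equal axis weights: the map is a pure isotropic scale s at P00
        spec = PhantomSpec(axis_weights=(1.0, 1.0, 1.0),
                           displacement_amplitude=0.0)
        b = generate_phantom(spec)
        s = 1.0 + spec._dilation()[0]
        sol = solve_displacement(b.mesh_for("P50"), lung_material,
                                 tumor_material(), b.boundary_field("P00"),
                                 FAST_SOLVER)
        f = extract_features(b, {"age": 60, "bmi": 22.0}, sol)
        for name in ("dx", "dy", "dz"):
            assert getattr(f, name) == pytest.approx(s - 1.0, rel=1e-6), name
        assert f.dSV == pytest.approx(1.0 / s - 1.0, rel=1e-6)

    def test_missing_phase_rejected(self, default_bundle, p00_solution):
        b = default_bundle
        crippled = PhaseBundle(
            spec=b.spec, reference_mesh=b.reference_mesh,
            phase_nodes={k: v for k, v in b.phase_nodes.items() if k != "P00"},
            displacements=b.displacements,
            surface_node_ids=b.surface_node_ids, times=b.times,
            truth_E=b.truth_E, truth_v=b.truth_v, mean_hu=b.mean_hu,
        )
        with pytest.raises((ValueError, KeyError)):
            extract_features(crippled, {"age": 1, "bmi": 1}, p00_solution)

    def test_volume_averaged_gradient_matches_affine(self, affine_bundle,
                                                     lung_material):
        mat = lung_material
        b = affine_bundle
        g = 1.0 + b.spec._dilation()
        sol = solve_displacement(b.mesh_for("P50"), mat, mat,
                                 b.boundary_field("P00"), FAST_SOLVER)
        F = volume_averaged_F(sol, "lung")
        np.testing.assert_allclose(F, np.diag(g), atol=1e-8)


class TestLasso:
    def test_age_effect_recovery(self):
        X, yE, yv = synthetic_feature_cohort(30, seed=321)
        results = lasso_loocv(X, {"avg_E": yE, "avg_v": yv})
        rE, rv = results["avg_E"], results["avg_v"]
        assert "Age" in rE.selected and rE.coef[6] < 0
        assert "Age" in rv.selected and rv.coef[6] > 0
        assert rE.loocv_mse >= 0.0

    def test_unselected_coefficients_exactly_zero(self):
        X, yE, _ = synthetic_feature_cohort(30, seed=321)
        est = LassoLoocvRegressor().fit(X, yE)
        unselected = np.setdiff1d(np.arange(11), est.selected_)
        assert np.all(est.coef_[unselected] == 0.0)

    def test_noise_free_single_predictor_mse_vanishes(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((20, 3))
        y = 2.0 * X[:, 1]
        est = LassoLoocvRegressor().fit(X, y)
        pred = est.predict(X)
        assert np.mean((pred - y) ** 2) < 1e-3

    def test_selection_path_monotone_in_penalty(self):
        from sklearn.linear_model import Lasso
        from sklearn.preprocessing import StandardScaler

        X, yE, _ = synthetic_feature_cohort(30, seed=11)
        Xs = StandardScaler().fit_transform(X)
        counts = []
        for alpha in np.logspace(-3, 0.5, 12):
            n = int(np.sum(Lasso(alpha=alpha, max_iter=50000)
                           .fit(Xs, yE).coef_ != 0))
            counts.append(n)
        assert np.all(np.diff(counts) <= 0)

    def test_small_cohort_rejected(self):
        X, yE, _ = synthetic_feature_cohort(4, seed=0)
        with pytest.raises(ValueError, match="at least 5"):
            LassoLoocvRegressor().fit(X, yE)

    def test_constant_target_rejected(self):
        X, _, _ = synthetic_feature_cohort(10, seed=0)
        with pytest.raises(ValueError, match="constant"):
            LassoLoocvRegressor().fit(X, np.ones(10))

    def test_features_frame_columns(self, default_bundle, p00_solution):
        f = extract_features(default_bundle, {"age": 50, "bmi": 20.0},
                             p00_solution)
        frame = features_frame([f])
        assert list(frame.columns) == list(FEATURE_NAMES)
        assert frame.shape == (1, 11)
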