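"""Constitutive models: Lame conversion, energies, stresses, tangents."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from lungmech.materials import (
    NH,
    SVK,
    IncompressibilityError,
    InvertedElementError,
    Material,
    cauchy_stress,
    lame_parameters,
    lame_to_young_poisson,
    linear_elastic_stress,
    material_tangent,
    pk1_stress,
    select_material_model,
    strain_energy,
    tumor_material,
)
from conftest import random_deformation_gradients


def finite_difference_pk1(F, mat, eps=1e-6):
    P = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            dF = np.zeros((3, 3))
            dF[i, j] = eps
            P[i, j] = (strain_energy(F + dF, mat) - strain_energy(F - dF, mat)) / (2 * eps)
    return P


class TestLameParameters:
    def test_reference_values(self):
        lam, mu = lame_parameters(3000.0, 0.3)
        assert lam == pytest.approx(1730.769230769, rel=1e-9)
        assert mu == pytest.approx(1153.846153846, rel=1e-9)

    def test_zero_poisson_corner(self):
        lam, mu = lame_parameters(1000.0, 0.0)
        assert lam == 0.0
        assert mu == 500.0

    def test_lambda_diverges_toward_incompressibility(self):
        lams = [lame_parameters(1000.0, v)[0] for v in (0.40, 0.45, 0.49, 0.499)]
        assert np.all(np.diff(lams) > 0)
        with pytest.raises(IncompressibilityError):
            lame_parameters(1000.0, 0.5)

    @given(E=st.floats(100.0, 1e8), v=st.floats(0.01, 0.49))
    @settings(max_examples=50, deadline=None)
    def test_round_trip(self, E, v):
        lam, mu = lame_parameters(E, v)
        E2, v2 = lame_to_young_poisson(lam, mu)
        assert E2 == pytest.approx(E, rel=1e-10)
        assert v2 == pytest.approx(v, rel=1e-10)


class TestModelSelection:
    @pytest.mark.parametrize(
        "J,expected",
        [(1.05, SVK), (1.1, SVK), (1.1001, NH), (1.3, NH)],
    )
    def test_threshold_rule(self, J, expected):
        model, J_out = select_material_model(1000.0, 1000.0 * J)
        assert model == expected
        assert J_out == pytest.approx(J, rel=1e-12)

    def test_positive_volumes_required(self):
        with pytest.raises(ValueError):
            select_material_model(0.0, 1.0)


class TestStrainEnergy:
    @pytest.mark.parametrize("model", [SVK, NH])
    def test_zero_at_identity(self, model):
        mat = Material(model, 5000.0, 0.35)
        assert strain_energy(np.eye(3), mat) == pytest.approx(0.0, abs=1e-15)

    def test_svk_uniaxial_hand_value(self):
        # E_GL = diag(0.105, 0, 0); W = lam/2 tr(E)^2 + mu tr(E^2)
        mat = Material(SVK, 2.5, 0.25)  # gives lam = mu = 1 Pa
        assert (mat.lam, mat.mu) == (pytest.approx(1.0), pytest.approx(1.0))
        W = strain_energy(np.diag([1.1, 1.0, 1.0]), mat)
        assert W == pytest.approx(0.0165375, abs=1e-10)

    def test_nh_uniaxial_hand_value(self):
        mat = Material(NH, 2.5, 0.25)
        W = strain_energy(np.diag([1.1, 1.0, 1.0]), mat)
        expected = 0.5 * 0.21 - np.log(1.1) + 0.5 * np.log(1.1) ** 2
        assert W == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("model", [SVK, NH])
    def test_frame_indifference(self, model):
        mat = Material(model, 4000.0, 0.3)
        rng = np.random.default_rng(11)
        for F in random_deformation_gradients(10, seed=5):
            R = Rotation.random(random_state=rng.integers(1 << 31)).as_matrix()
            assert strain_energy(R @ F, mat) == pytest.approx(
                strain_energy(F, mat), rel=1e-10, abs=1e-12
            )

    def test_inverted_gradient_rejected(self):
        mat = Material(NH, 5000.0, 0.3)
        with pytest.raises(InvertedElementError):
            strain_energy(np.diag([-1.0, 1.0, 1.0]), mat)


class TestPK1Stress:
    @pytest.mark.parametrize("model", [SVK, NH])
    def test_zero_at_identity(self, model):
        mat = Material(model, 5000.0, 0.35)
        np.testing.assert_allclose(pk1_stress(np.eye(3), mat), 0.0, atol=1e-12)

    @pytest.mark.parametrize("model", [SVK, NH])
    def test_matches_energy_gradient(self, model):
        mat = Material(model, 3000.0, 0.3)
        for F in random_deformation_gradients(20, seed=7):
            P = pk1_stress(F, mat)
            P_fd = finite_difference_pk1(F, mat)
            np.testing.assert_allclose(P, P_fd, rtol=1e-6,
                                       atol=1e-6 * np.abs(P).max())

    @pytest.mark.parametrize("model", [SVK, NH])
    def test_small_strain_linearization(self, model):
        rng = np.random.default_rng(3)
        mat = Material(model, 5000.0, 0.3)
        A = rng.standard_normal((3, 3))
        eps = 1e-4
        F = np.eye(3) + eps * A
        P = pk1_stress(F, mat)
        P_lin = linear_elastic_stress(eps * A, mat)
        assert np.abs(P - P_lin).max() < 0.01 * np.abs(P_lin).max()

    @pytest.mark.parametrize("model", [SVK, NH])
    def test_cauchy_stress_symmetric(self, model):
        mat = Material(model, 3000.0, 0.35)
        for F in random_deformation_gradients(10, seed=9):
            s = cauchy_stress(F, mat)
            assert np.abs(s - s.T).max() <= 1e-8 * np.abs(s).max()

    @pytest.mark.parametrize("model", [SVK, NH])
    def test_tangent_matches_stress_gradient(self, model):
        mat = Material(model, 2000.0, 0.25)
        eps = 1e-6
        for F in random_deformation_gradients(5, seed=13):
            A = material_tangent(F, mat)
            for k in range(3):
                for L in range(3):
                    dF = np.zeros((3, 3))
                    dF[k, L] = eps
                    dP = (pk1_stress(F + dF, mat) - pk1_stress(F - dF, mat)) / (2 * eps)
                    np.testing.assert_allclose(A[:, :, k, L], dP, rtol=2e-5,
                                               atol=1e-4 * np.abs(A).max())


def test_tumor_material_reference_values():
    mat = tumor_material()
    assert mat.E == pytest.approx(49e6)
    assert mat.v == pytest.approx(0.4)
    assert mat.model == SVK
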