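"""Hyperelastic constitutive models for lung and tumor tissue.

Two compressible isotropic strain-energy densities are provided:

* Saint-Venant-Kirchhoff (SVK), quadratic in the Green-Lagrange strain
  ``E = (F^T F - I)/2``::

      W = lam/2 * tr(E)^2 + mu * tr(E^2)

* Neo-Hookean (NH)::

      W = mu/2 * (I1 - 3) - mu * ln(J) + lam/2 * ln(J)^2

with ``I1 = tr(F^T F)`` and ``J = det(F)``.  The Lame parameters derive from
Young's modulus E and Poisson's ratio v in the standard way.  The model is
selected per patient from the exhale-to-inhale lung volume ratio
``J = V(P00)/V(P50)``: SVK for J <= 1.1 (moderate deformation), NH above.

All stress routines return the first Piola-Kirchhoff (nominal) stress
``P = dW/dF`` and are vectorized over leading axes of ``F``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SVK = "SVK"
NH = "NH"

#: Material-model switch point on the lung volume ratio V(P00)/V(P50).
J_MODEL_THRESHOLD = 1.1

#: Default tumor properties: stiff, nearly incompressible linear-elastic
#: inclusion (modeled as SVK, which reduces to linear elasticity at the
#: small strains a 49 MPa inclusion experiences inside 2-11 kPa lung).
TUMOR_E_PA = 49e6
TUMOR_V = 0.4


class IncompressibilityError(ValueError):
    """Poisson's ratio at or beyond the incompressible limit v = 0.5."""


class InvertedElementError(ValueError):
    """Deformation gradient with non-positive determinant."""


def lame_parameters(E: float, v: float) -> tuple[float, float]:
    """Lame parameters (lam, mu) from Young's modulus and Poisson's ratio.

    lam = v E / ((1+v)(1-2v)),  mu = E / (2(1+v)).
    """
    if E <= 0:
        raise ValueError(f"Young's modulus must be positive, got {E}")
    if v >= 0.5:
        raise IncompressibilityError(
            f"Poisson's ratio must be below the incompressible limit 0.5, got {v}"
        )
    if v < 0:
        raise ValueError(f"negative Poisson's ratio unsupported, got {v}")
    lam = v * E / ((1 + v) * (1 - 2 * v))
    mu = E / (2 * (1 + v))
    return lam, mu


def lame_to_young_poisson(lam: float, mu: float) -> tuple[float, float]:
    """Inverse of :func:`lame_parameters`."""
    E = mu * (3 * lam + 2 * mu) / (lam + mu)
    v = lam / (2 * (lam + mu))
    return E, v


@dataclass(frozen=True)
class Material:
    """Isotropic hyperelastic material with derived Lame parameters.

    Parameters are stored in Pa; ``model`` is ``"SVK"`` or ``"NH"``.
    """

    model: str
    E: float
    v: float
    lam: float = field(init=False)
    mu: float = field(init=False)

    def __post_init__(self) -> None:
        if self.model not in (SVK, NH):
            raise ValueError(f"unknown material model {self.model!r}")
        lam, mu = lame_parameters(self.E, self.v)
        object.__setattr__(self, "lam", lam)
        object.__setattr__(self, "mu", mu)


def tumor_material() -> Material:
    """Default stiff tumor inclusion (49 MPa, v = 0.4)."""
    return Material(SVK, TUMOR_E_PA, TUMOR_V)


def select_material_model(v_exhale: float, v_inhale: float) -> tuple[str, float]:
    """Choose SVK vs NH from the lung volume ratio J = V_inhale / V_exhale.

    Returns ``(model_name, J)``; SVK for J <= 1.1 inclusive, NH otherwise.
    """
    if v_exhale <= 0 or v_inhale <= 0:
        raise ValueError("volumes must be positive")
    J = v_inhale / v_exhale
    return (SVK if J <= J_MODEL_THRESHOLD else NH), J


def _check_F(F: np.ndarray) -> np.ndarray:
    F = np.asarray(F, dtype=float)
    J = np.linalg.det(F)
    if np.any(J <= 0):
        idx = np.argwhere(np.atleast_1d(J) <= 0)
        raise InvertedElementError(
            f"det(F) <= 0 on {len(idx)} element(s), first index {idx[0].tolist()}"
        )
    return F


def strain_energy(F: np.ndarray, mat: Material) -> float | np.ndarray:
    """Strain energy density W(F) in Pa; vectorized over leading axes."""
    F = _check_F(F)
    lam, mu = mat.lam, mat.mu
    if mat.model == SVK:
        C = np.swapaxes(F, -1, -2) @ F
        Egl = (C - np.eye(3)) / 2.0
        trE = np.trace(Egl, axis1=-2, axis2=-1)
        trE2 = np.einsum("...ij,...ji->...", Egl, Egl)
        W = 0.5 * lam * trE**2 + mu * trE2
    else:
        I1 = np.einsum("...ij,...ij->...", F, F)
        lnJ = np.log(np.linalg.det(F))
        W = 0.5 * mu * (I1 - 3.0) - mu * lnJ + 0.5 * lam * lnJ**2
    return W if np.ndim(W) else float(W)


def pk1_stress(F: np.ndarray, mat: Material) -> np.ndarray:
    """First Piola-Kirchhoff stress P = dW/dF in Pa; vectorized."""
    F = _check_F(F)
    lam, mu = mat.lam, mat.mu
    if mat.model == SVK:
        C = np.swapaxes(F, -1, -2) @ F
        Egl = (C - np.eye(3)) / 2.0
        trE = np.trace(Egl, axis1=-2, axis2=-1)
        S = lam * trE[..., None, None] * np.eye(3) + 2.0 * mu * Egl
        return F @ S
    Finv_T = np.swapaxes(np.linalg.inv(F), -1, -2)
    lnJ = np.log(np.linalg.det(F))[..., None, None]
    return mu * F + (lam * lnJ - mu) * Finv_T


def cauchy_stress(F: np.ndarray, mat: Material) -> np.ndarray:
    """Cauchy stress sigma = J^-1 P F^T; symmetric by construction."""
    F = _check_F(F)
    P = pk1_stress(F, mat)
    J = np.linalg.det(F)[..., None, None]
    return P @ np.swapaxes(F, -1, -2) / J


def material_tangent(F: np.ndarray, mat: Material) -> np.ndarray:
    """Tangent modulus A_iJkL = dP_iJ/dF_kL; vectorized, shape (...,3,3,3,3).

    Exact closed forms for both models; used to assemble the Newton
    stiffness matrix.
    """
    F = _check_F(F)
    lam, mu = mat.lam, mat.mu
    eye = np.eye(3)
    if mat.model == SVK:
        C = np.swapaxes(F, -1, -2) @ F
        Egl = (C - eye) / 2.0
        trE = np.trace(Egl, axis1=-2, axis2=-1)
        S = lam * trE[..., None, None] * eye + 2.0 * mu * Egl
        B = F @ np.swapaxes(F, -1, -2)
        A = (
            np.einsum("ik,...JL->...iJkL", eye, S)
            + lam * np.einsum("...iJ,...kL->...iJkL", F, F)
            + mu * np.einsum("...iL,...kJ->...iJkL", F, F)
            + mu * np.einsum("...ik,JL->...iJkL", B, eye)
        )
        return A
    G = np.swapaxes(np.linalg.inv(F), -1, -2)  # F^{-T}
    lnJ = np.log(np.linalg.det(F))
    coeff = (lam * lnJ - mu)[..., None, None, None, None]
    A = (
        mu * np.einsum("ik,JL->iJkL", eye, eye)
        + lam * np.einsum("...iJ,...kL->...iJkL", G, G)
        - coeff * np.einsum("...iL,...kJ->...iJkL", G, G)
    )
    return A


def linear_elastic_stress(grad_u: np.ndarray, mat: Material) -> np.ndarray:
    """Small-strain isotropic stress lam*tr(eps)*I + 2*mu*eps, eps = sym(grad_u)."""
    grad_u = np.asarray(grad_u, dtype=float)
    eps = 0.5 * (grad_u + np.swapaxes(grad_u, -1, -2))
    tr = np.trace(eps, axis1=-2, axis2=-1)[..., None, None]
    return mat.lam * tr * np.eye(3) + 2.0 * mat.mu * eps
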