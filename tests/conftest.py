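"""Shared fixtures: phantom bundles and converged reference solves.

Session-scoped so the expensive FEM solves are shared across test modules.
"""

from __future__ import annotations

import numpy as np
import pytest

from lungmech.fem import SolverConfig, solve_displacement
from lungmech.materials import Material, tumor_material
from lungmech.mesh import TetMesh
from lungmech.phantom import PhantomSpec, generate_phantom

FAST_SOLVER = SolverConfig(n_increments=2)


@pytest.fixture(scope="session")
def default_bundle():
    """Default breathing phantom (~2k tets, 13% volume change)."""
    return generate_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def affine_bundle():
    """Phantom without caudal grading: the motion map is exactly affine,
    so it coincides with the elastic equilibrium (analytic oracle holds)."""
    return generate_phantom(PhantomSpec(displacement_amplitude=0.0))


@pytest.fixture(scope="session")
def lung_material():
    return Material("NH", 5000.0, 0.35)


@pytest.fixture(scope="session")
def p00_solution(default_bundle, lung_material):
    """Converged P50 -> P00 solve on the default phantom."""
    return solve_displacement(
        default_bundle.mesh_for("P50"),
        lung_material,
        tumor_material(),
        default_bundle.boundary_field("P00"),
        FAST_SOLVER,
    )


@pytest.fixture()
def unit_cube_mesh():
    """Unit cube as a 5-tet decomposition (exact volume 1, area 6)."""

    def make(origin=(0.0, 0.0, 0.0), region="lung"):
        o = np.asarray(origin, dtype=float)
        verts = o + np.array(
            [[x, y, z] for x in (0, 1) for y in (0, 1) for z in (0, 1)],
            dtype=float,
        )
        tets = np.array([[0, 1, 2, 4], [1, 2, 3, 7], [1, 4, 5, 7],
                         [2, 4, 6, 7], [1, 2, 4, 7]])
        return TetMesh(verts, tets, np.array([region] * 5, dtype=object))

    return make


def random_deformation_gradients(n: int, seed: int, scale: float = 0.3) -> np.ndarray:
    """Random admissible (det > 0) deformation gradients near identity."""
    rng = np.random.default_rng(seed)
    out = []
    while len(out) < n:
        F = np.eye(3) + scale * rng.standard_normal((3, 3))
        if np.linalg.det(F) > 0.05:
            out.append(F)
    return np.array(out)
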