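"""Shared fixtures: small phantoms for unit tests, the full desk-scale
phantom study (built once per session) for the end-to-end checks."""

from __future__ import annotations

import numpy as np
import pytest

from ecgikit.geometry import TriangleMesh, icosphere, torso_ventricle_phantom
from ecgikit.study import StudyConfig, build_phantom_assets, run_default_study


@pytest.fixture(scope="session")
def small_phantom():
    """Coarse phantom (162-node heart, 642-node torso) for fast tests."""
    return torso_ventricle_phantom(resolution=2)


@pytest.fixture(scope="session")
def sphere_pair():
    """Concentric spheres r=50/200 mm at 1280 faces each (BEM oracle setup)."""
    heart = icosphere(50.0, 3)
    heart.role = "heart"
    torso = icosphere(200.0, 3)
    torso.role = "torso"
    return heart, torso


@pytest.fixture(scope="session")
def flat_square_mesh():
    """A regularly triangulated unit square in the z=0 plane (open mesh)."""
    k = 8
    xs = np.linspace(0.0, 1.0, k + 1)
    xx, yy = np.meshgrid(xs, xs, indexing="ij")
    verts = np.column_stack([xx.ravel(), yy.ravel(), np.zeros((k + 1) ** 2)])
    faces = []
    for i in range(k):
        for j in range(k):
            a = i * (k + 1) + j
            b = a + 1
            c = a + (k + 1)
            d = c + 1
            faces.append([a, b, d])
            faces.append([a, d, c])
    interior = [
        i * (k + 1) + j for i in range(1, k) for j in range(1, k)
    ]
    return TriangleMesh(verts, np.asarray(faces)), np.asarray(interior)


@pytest.fixture(scope="session")
def sphere_refinement_errors():
    """Relative RMS dipole-oracle error of the BEM transfer at three mesh
    refinement levels (icosphere subdivisions 2, 3, 4), computed once.

    The coarsest (subdivision-1) pair is excluded: icosahedral symmetry makes
    the 80-face discretisation superconvergent for the pure l=1 dipole field,
    so the asymptotic refinement trend starts one level up.
    """
    from ecgikit.forward import assemble_transfer

    def dipole(verts, outer_radius):
        r = np.linalg.norm(verts, axis=1)
        return verts[:, 2] / r / (4 * np.pi) * (1.0 / r**2 + 2.0 * r / outer_radius**3)

    errors = {}
    for sub in (2, 3, 4):
        heart = icosphere(50.0, sub)
        heart.role = "heart"
        torso = icosphere(200.0, sub)
        torso.role = "torso"
        A = assemble_transfer(torso, heart)
        x = dipole(heart.vertices, 200.0)
        y = dipole(torso.vertices, 200.0)
        errors[sub] = float(
            np.linalg.norm(A.entries @ x - y) / np.linalg.norm(y)
        )
    return errors


@pytest.fixture(scope="session")
def study_assets():
    """Geometry assets of the default desk-scale phantom (shared, expensive)."""
    return build_phantom_assets(StudyConfig.lead_size_arm())


@pytest.fixture(scope="session")
def default_study(study_assets):
    """The default two-arm study table (shared, expensive)."""
    return run_default_study(assets=study_assets)
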