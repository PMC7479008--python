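"""Shared fixtures: canonical planes, simple meshes, phantom cache."""

import numpy as np
import pytest
import trimesh

from craniocurve.geometry import CuttingPlane, LandmarkSet
from craniocurve.outline import Outline


@pytest.fixture
def z0_plane() -> CuttingPlane:
    """The canonical z=0 plane with anterior +x."""
    return CuttingPlane(
        origin=np.zeros(3),
        normal=np.array([0.0, 0.0, 1.0]),
        u_axis=np.array([1.0, 0.0, 0.0]),
        v_axis=np.array([0.0, 1.0, 0.0]),
    )


@pytest.fixture
def flat_landmarks() -> LandmarkSet:
    """Coplanar (z=0) landmarks: eyes anterior (+x), porion posterior-lateral."""
    return LandmarkSet(
        ex_left=[60.0, 40.0, 0.0],
        ex_right=[60.0, -40.0, 0.0],
        po_left=[-20.0, 55.0, 0.0],
        po_right=[-20.0, -55.0, 0.0],
    )


@pytest.fixture(scope="session")
def sphere_mesh() -> trimesh.Trimesh:
    """Unit-test sphere, radius 50 mm, fine enough for 1 % slice accuracy."""
    return trimesh.creation.icosphere(subdivisions=4, radius=50.0)


def regular_polygon(n: int, radius: float = 1.0) -> np.ndarray:
    ang = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return radius * np.column_stack([np.cos(ang), np.sin(ang)])


@pytest.fixture
def circle_outline(z0_plane) -> Outline:
    return Outline(vertices=regular_polygon(256, 80.0), plane=z0_plane)


@pytest.fixture(scope="session")
def noise_free_phantoms():
    """One noise-free phantom per phenotype (session-cached: generation and
    slicing dominate test time)."""
    from craniocurve.synthetic import PHENOTYPE_SPECS, generate_phantom

    return {label: generate_phantom(spec) for label, spec in PHENOTYPE_SPECS.items()}
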