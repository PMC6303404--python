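import numpy as np
import pytest
import trimesh

from perivasc.volume_io import TriMesh


@pytest.fixture(scope="session")
def cylinder_mesh():
    """Axial cylinder r=5 um through the centre of a 100 um box."""
    cyl = trimesh.creation.cylinder(radius=5.0, height=100.0, sections=64)
    cyl.apply_translation([50.0, 50.0, 50.0])
    return TriMesh.from_trimesh(cyl)


@pytest.fixture(scope="session")
def cylinder_interior():
    def interior(pts):
        pts = np.atleast_2d(pts)
        return np.linalg.norm(pts[:, :2] - 50.0, axis=1) < 5.0

    return interior


@pytest.fixture(scope="session")
def box_100():
    return (np.zeros(3), np.full(3, 100.0))


@pytest.fixture(scope="session")
def torus_mesh_500():
    """A 500-face torus for distance-oracle comparisons."""
    tor = trimesh.creation.torus(
        major_radius=10.0, minor_radius=3.0, major_sections=25, minor_sections=10
    )
    assert len(tor.faces) == 500
    return TriMesh.from_trimesh(tor)
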