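import numpy as np
import pytest
import trimesh

from aneumorph import SacSpec, SurfaceMesh, NeckContour, make_sac


@pytest.fixture(scope="session")
def hemisphere_fine():
    """Unit hemisphere geometry + closed-form truth at the finest grid."""
    return make_sac(SacSpec(family="hemisphere", radius=1.0,
                            resolution=(128, 64)))


@pytest.fixture(scope="session")
def hemisphere_coarse():
    return make_sac(SacSpec(family="hemisphere", radius=1.0,
                            resolution=(32, 16)))


@pytest.fixture(scope="session")
def unit_cube():
    """Closed unit cube (volume 1, area 6), consistently wound."""
    box = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
    return SurfaceMesh(vertices=np.asarray(box.vertices),
                       faces=np.asarray(box.faces))


@pytest.fixture(scope="session")
def open_box_sac(unit_cube):
    """Unit cube with the bottom face removed: a square-neck box sac."""
    zmin = unit_cube.vertices[:, 2].min()
    bottom = np.all(
        np.isclose(unit_cube.vertices[unit_cube.faces][:, :, 2], zmin), axis=1)
    sac = SurfaceMesh(unit_cube.vertices, unit_cube.faces[~bottom])
    corners = unit_cube.vertices[np.isclose(unit_cube.vertices[:, 2], zmin)]
    # order the 4 bottom corners into a simple square ring
    ang = np.arctan2(corners[:, 1] - corners[:, 1].mean(),
                     corners[:, 0] - corners[:, 0].mean())
    neck = NeckContour(points=corners[np.argsort(ang)])
    return sac, neck


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
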