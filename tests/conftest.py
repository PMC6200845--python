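import numpy as np
import pytest

from cortimap.fixtures import FixtureSpec, make_solid_shell, make_target_pair


@pytest.fixture(scope="session")
def sphere_spec():
    """Sphere shell, latitudinal thickness, refinement 2, seed 1."""
    return FixtureSpec(
        kind="sphere",
        semi_axes=(10.0, 10.0, 10.0),
        level=2,
        thickness="latitudinal",
        thickness_params={"t0": 1.5, "t1": 0.5},
        deformation="bulge",
        seed=1,
    )


@pytest.fixture(scope="session")
def sphere_shell(sphere_spec):
    return make_solid_shell(sphere_spec)


@pytest.fixture(scope="session")
def sphere_pair(sphere_spec):
    return make_target_pair(sphere_spec)


@pytest.fixture(scope="session")
def ellipsoid_spec():
    """Default hip-scale ellipsoid with latitudinal field and bulge."""
    return FixtureSpec(seed=1)


@pytest.fixture(scope="session")
def ellipsoid_shell(ellipsoid_spec):
    return make_solid_shell(ellipsoid_spec)


@pytest.fixture(scope="session")
def ellipsoid_pair(ellipsoid_spec):
    return make_target_pair(ellipsoid_spec)


def outer_nodes(layer):
    """(ids, coords) of a layer's outer skin, in ascending id order."""
    ids = sorted(layer.outer_surface_nodes)
    return ids, layer.coords[layer.index_of(ids)]


@pytest.fixture
def single_hexa_k(tmp_path):
    """Minimal keyword file: unit cube, one hexahedron."""
    text = """$ minimal one-element shell layer
*KEYWORD
*NODE
1,0.0,0.0,0.0
2,1.0,0.0,0.0
3,1.0,1.0,0.0
4,0.0,1.0,0.0
5,0.0,0.0,1.0
6,1.0,0.0,1.0
7,1.0,1.0,1.0
8,0.0,1.0,1.0
*ELEMENT_SOLID
1,1,1,2,3,4,5,6,7,8
*END
"""
    p = tmp_path / "hexa.k"
    p.write_text(text)
    return p
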