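import numpy as np
import pytest
import trimesh
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from airforge.synth import PhantomSpec, PocketCavity, TreeSpec, TubeCavity, make_ct_phantom, make_tube_tree


@pytest.fixture(scope="session")
def icosphere():
    """Unit icosphere at marching-cubes-like vertex density."""
    return trimesh.creation.icosphere(subdivisions=4)


@pytest.fixture(scope="session")
def icosphere_coarse():
    return trimesh.creation.icosphere(subdivisions=2)


@pytest.fixture(scope="session")
def closed_tree2():
    return make_tube_tree(TreeSpec(generations=2))


@pytest.fixture(scope="session")
def open_tree3():
    return make_tube_tree(TreeSpec(generations=3, open_ends=True))


@pytest.fixture(scope="session")
def straight_tube():
    return make_tube_tree(TreeSpec(generations=0, root_radius_mm=4.0, root_length_mm=40.0))


@pytest.fixture(scope="session")
def multi_body_phantom():
    """Tube plus one oral-sized pocket and one sub-threshold pocket.

    Cavity centers are deliberately off-lattice: rasterized voxel counts of
    lattice-aligned primitives are a known worst case of center sampling.
    """
    spec = PhantomSpec(
        shape=(64, 64, 96),
        cavities=[
            TubeCavity((32.3, 31.7, 2.0), (32.3, 31.7, 94.0), 30.0),
            PocketCavity((15.4, 15.6, 20.3), 5.0),
            PocketCavity((48.6, 15.2, 70.4), 1.0),
        ],
    )
    vol, masks = make_ct_phantom(spec, seed=3)
    return spec, vol, masks
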