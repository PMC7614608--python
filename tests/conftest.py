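import numpy as np
import pytest

from globulegeom.synthetic_scenes import (
    Particle,
    Scene,
    SceneConfig,
    default_rigid_model,
)


@pytest.fixture(scope="session")
def model():
    """Default C2-symmetric pseudo-atom complex used throughout."""
    return default_rigid_model()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_shape_scene(semi_axes, rotation=None, model=None):
    """A one-particle scene with a given ellipsoid, for density rendering."""
    model = model or default_rigid_model()
    return Scene(
        particles=[
            Particle(
                center=np.zeros(3),
                semi_axes=np.asarray(semi_axes, float),
                rotation=np.eye(3) if rotation is None else rotation,
            )
        ],
        poses=[],
        pose_particle_ids=np.array([], dtype=int),
        ground_truth_pairs=[],
        model=model,
        config=SceneConfig(n_particles=1, seed=0),
    )


# half-voxel-offset origin so the sampling lattice straddles the surface
def centered_origin(extent, voxel=10.0):
    return np.array([-(extent + voxel / 2)] * 3)
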