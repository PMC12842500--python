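import numpy as np
import pytest
from hypothesis import settings

from stoneburden.phantom import Ellipsoid, PhantomSpec, StoneSpec

settings.register_profile("det", derandomize=True, deadline=None)
settings.load_profile("det")


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


def sphere_phantom(spacing=(1.0, 1.0, 1.0), radius=10.0,
                   center=(20.33, 20.47, 20.61), extent=42.0,
                   noise_sd=0.0, seed=0, hu=400.0):
    """One spherical stone centered in a single spherical 'kidney'."""
    shape = tuple(int(np.floor(extent / s)) + 1 for s in spacing)
    return PhantomSpec(
        grid_shape=shape,
        voxel_spacing=spacing,
        kidneys={"right": Ellipsoid(center, (18.0, 18.0, 18.0))},
        stones=[StoneSpec.sphere("right", center, radius, hu)],
        noise_sd=noise_sd,
        seed=seed,
    )


def two_kidney_phantom(noise_sd=0.0, seed=0, spacing=(1.0, 1.0, 1.0),
                       stone_radii=(6.0, 5.0)):
    """Two ellipsoidal kidneys, one stone each, on a 64 mm cube."""
    shape = tuple(int(np.floor(64.0 / s)) + 1 for s in spacing)
    kidneys = {
        "right": Ellipsoid((18.0, 32.0, 32.0), (12.0, 12.0, 25.0)),
        "left": Ellipsoid((46.0, 32.0, 32.0), (12.0, 12.0, 25.0)),
    }
    stones = [
        StoneSpec.sphere("right", (18.0, 32.0, 26.0), stone_radii[0]),
        StoneSpec.sphere("left", (46.0, 32.0, 40.0), stone_radii[1]),
    ]
    return PhantomSpec(grid_shape=shape, voxel_spacing=spacing,
                       kidneys=kidneys, stones=stones,
                       noise_sd=noise_sd, seed=seed)


@pytest.fixture
def noise_free_phantom():
    return two_kidney_phantom()
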