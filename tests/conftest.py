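import numpy as np
import pytest

from lungembed.phantom import PhantomSpec, generate_phantom
from lungembed.segmentation import EmbeddednessParams


@pytest.fixture(scope="session")
def small_phantom():
    """64³ phantom with certified truth (shared; treat as read-only)."""
    return generate_phantom(PhantomSpec(n=64, rng_seed=1))


@pytest.fixture(scope="session")
def acceptance_phantom():
    """128³ phantom at the published 0.5 mm spacing (shared; read-only)."""
    return generate_phantom(PhantomSpec(n=128, spacing_mm=0.5, rng_seed=1))


def random_hu_volume(rng: np.random.Generator, dims) -> np.ndarray:
    """A blocky random HU field mixing witness-range and out-of-range values.

    Values are drawn from a palette straddling the default witness interval
    and smoothed into connected blobs, so random volumes contain structures
    the embeddedness criterion actually discriminates.
    """
    palette = np.array([-1000, -900, -700, -300, -100, 40, 200, 1000], dtype=np.int16)
    coarse_dims = tuple(max(1, d // 3) for d in dims)
    coarse = rng.integers(0, len(palette), size=coarse_dims)
    reps = tuple(-(-d // c) for d, c in zip(dims, coarse_dims))
    field = np.kron(coarse, np.ones(reps, dtype=int))[: dims[0], : dims[1], : dims[2]]
    # sprinkle voxel-level salt so fields are not purely blocky
    salt = rng.random(dims) < 0.1
    field[salt] = rng.integers(0, len(palette), size=int(salt.sum()))
    return palette[field]


def random_params(rng: np.random.Generator) -> EmbeddednessParams:
    return EmbeddednessParams(
        lung_min=-1500,
        lung_max=int(rng.choice([-200, -500])),
        max_ray_steps=int(rng.integers(1, 7)),
        max_misses=int(rng.integers(0, 7)),
        include_self=bool(rng.integers(0, 2)),
    )
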