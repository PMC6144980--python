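import numpy as np
import pytest

import nchroma as nc


@pytest.fixture(scope="session")
def grid():
    return nc.default_grid()


@pytest.fixture(scope="session")
def flat_illuminant(grid):
    return nc.builtin_illuminant("flat", grid)


@pytest.fixture(scope="session")
def d65(grid):
    return nc.builtin_illuminant("D65", grid)


@pytest.fixture(scope="session")
def background_7pct(grid):
    return nc.flat_reflectance(0.07, grid)


@pytest.fixture(scope="session")
def leaf(grid):
    return nc.leaf_background(grid)


@pytest.fixture(scope="session")
def trichromat(grid):
    """Synthetic UV/blue/green trichromat with honeybee-style noise."""
    return nc.PhotoreceptorSet.from_gaussians(
        (350.0, 440.0, 540.0), sd=45.0, grid=grid, noise=(0.13, 0.06, 0.12)
    )


@pytest.fixture(scope="session")
def bee_like(grid):
    return nc.honeybee_like_receptors(grid)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260929)
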