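import numpy as np
import pytest

import spotcall as sc
from spotcall.synthetic import SceneSpec, SpotSpec

# The standard fixture slide: 20 spots, 8 seeded positive, 10 negative,
# 2 sparse (below the 10-cell filter).  Well-separated regime.
STANDARD_SEED = 11
# The hard fixture: heavier nucleus overlap, more RBC blobs, more noise.
HARD_SEED = 23


def standard_scene() -> SceneSpec:
    return sc.grid_scene(5, 4, seed=STANDARD_SEED, sparse_spots=2, positive_spot_fraction=8 / 18)


def hard_scene() -> SceneSpec:
    return sc.grid_scene(
        5,
        4,
        seed=HARD_SEED,
        sparse_spots=2,
        positive_spot_fraction=8 / 18,
        separation_factor=1.25,
        rbc_per_spot=3,
        noise_sigma=4.0,
    )


@pytest.fixture(scope="session")
def standard_render():
    spec = standard_scene()
    image, grid, truth = sc.render_slide(spec)
    return spec, image, grid, truth


@pytest.fixture(scope="session")
def hard_render():
    spec = hard_scene()
    image, grid, truth = sc.render_slide(spec)
    return spec, image, grid, truth


def single_spot_scene(n_nuclei, seed, *, positive_fraction=0.0, size=130, **overrides):
    return SceneSpec(
        width=size,
        height=size,
        seed=seed,
        spots=(SpotSpec(size // 2, size // 2, n_nuclei, positive_fraction),),
        separation_factor=overrides.pop("separation_factor", 1.7),
        rbc_per_spot=overrides.pop("rbc_per_spot", 0),
        **overrides,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
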