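import numpy as np
import pytest

from petprior import (
    PhantomConfig,
    VolumeGrid,
    generate_phantom,
    hard_case_config,
)

SPACING = (2.04, 2.04, 3.00)


def small_hard_case(seed: int, **overrides) -> PhantomConfig:
    """Hard-case phantom on a 48³ grid sized so the body fits."""
    defaults = dict(grid_shape=(48, 48, 48), body_axes_mm=(40.0, 34.0))
    defaults.update(overrides)
    return hard_case_config(seed=seed, **defaults)


@pytest.fixture(scope="session")
def phantom_sample():
    """One mid-size phantom with 3 ordinary lesions."""
    return generate_phantom(PhantomConfig(n_lesions=3, seed=7))


@pytest.fixture(scope="session")
def hard_sample():
    """One hard-case phantom (sub-1 ml lesion + barely-avid lesion)."""
    return generate_phantom(small_hard_case(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_mask_volume(rng, max_side=12, p=0.3, spacing=SPACING) -> VolumeGrid:
    shape = tuple(rng.integers(3, max_side + 1, size=3))
    vals = (rng.random(shape) < p).astype(np.uint8)
    return VolumeGrid(vals, spacing)
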