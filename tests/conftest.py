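import numpy as np
import pytest

from pettex.imaging_io import ImageVolume, RoiMask
from pettex.synthetic_cohort import CohortConfig, PhantomSpec, generate_cohort, generate_phantom


@pytest.fixture(scope="session")
def default_cohort():
    """One default 20+10 synthetic cohort, shared across tests."""
    return generate_cohort(CohortConfig(seed=42))


@pytest.fixture(scope="session")
def small_cohort():
    """A cheap 6+6 cohort on a small grid for I/O and pipeline plumbing tests."""
    cfg = CohortConfig(
        n_cr=6, n_noncr=6, seed=7,
        grid_shape=(20, 20, 20), tumor_radius_mm=14.0, radius_sigma=0.15,
    )
    return generate_cohort(cfg)


@pytest.fixture
def noisy_phantom():
    spec = PhantomSpec(grid_shape=(24, 24, 24), tumor_radius_mm=18.0,
                       heterogeneity_sd=0.4, correlation_length_mm=6.0)
    return generate_phantom(spec, seed=11)


def random_masked_image(rng, shape=(6, 7, 8), mask_density=0.6):
    """A small random image + random nonempty mask for oracle comparisons."""
    img = ImageVolume(rng.uniform(10, 500, size=shape), (4.0, 4.0, 4.0))
    flags = rng.random(shape) < mask_density
    if not flags.any():
        flags[tuple(s // 2 for s in shape)] = True
    return img, RoiMask(flags, (4.0, 4.0, 4.0))
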