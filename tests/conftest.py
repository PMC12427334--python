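import numpy as np
import pytest

from pigcycle.morphometrics import BinaryMask
from pigcycle.synthetic import CohortSpec, SilhouetteSpec, generate_cohort, render_mask


@pytest.fixture(scope="session")
def ellipse_mask_200_100():
    """Noise-free analytic ellipse a=200, b=100 on a 640x640 canvas."""
    return render_mask(SilhouetteSpec(semi_major_px=200, semi_minor_px=100))


@pytest.fixture(scope="session")
def small_cohort():
    """Seeded 63-pig cohort with 3 kg weigh-in noise (the recovery setting)."""
    return generate_cohort(CohortSpec(seed=7, noise_sd_weight=3.0))


@pytest.fixture()
def rectangle_mask():
    """Axis-aligned solid 100x50 px rectangle mask."""
    grid = np.zeros((80, 130), dtype=np.uint8)
    grid[15:65, 15:115] = 1
    return BinaryMask(grid=grid, name="rect100x50")
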