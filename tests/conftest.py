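import numpy as np
import pytest

from polarrad.discretize import DiscretizedMap
from polarrad.io import PolarMap, centered_disc_mask
from polarrad.synthetic import CohortSpec


def disc_map(size: int = 32, value: float = 100.0, radius: float | None = None) -> PolarMap:
    """A constant-valued disc map (peak-normalized by construction)."""
    mask = centered_disc_mask((size, size), radius if radius is not None else size / 2 - 2)
    pixels = np.where(mask, value, 0.0)
    return PolarMap.from_raw(pixels, mask)


def dmap_from_levels(levels, n_bins: int = 3) -> DiscretizedMap:
    """Wrap an integer level grid (0 = outside mask) for texture tests."""
    return DiscretizedMap(levels=np.asarray(levels, dtype=np.int32), n_bins=n_bins, bounds=(0.0, 1.0))


@pytest.fixture
def constant_disc() -> PolarMap:
    return disc_map()


@pytest.fixture
def small_spec() -> CohortSpec:
    """A small-but-valid cohort for fast end-to-end tests."""
    return CohortSpec(
        n_group_low_mfr=8,
        n_group_high_mfr=8,
        n_validation=4,
        image_size=32,
        seed=7,
    )
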