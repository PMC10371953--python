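"""Gray-level discretization of polar-map uptake values.

Texture matrices operate on integer gray levels. This module maps the
continuous relative-uptake values inside the region of interest to integer
levels 1..n_bins by relative (min-max) resampling between the masked
minimum and maximum:

    level(x) = 1 + floor(n_bins * (u(x) - min) / (max - min))

with the pixel at the maximum clamped into the top bin (bins are half-open,
closed at the top end). A constant region maps entirely to level 1. This
matches the relative-resampling mode appropriate for peak-normalized
images; absolute bounds can be supplied for the fixed-bounds mode.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import PolarMap

#: The five bin depths used throughout the analysis.
STANDARD_BIN_DEPTHS = (8, 16, 32, 64, 128)


@dataclass
class DiscretizedMap:
    """Integer gray-level grid: 0 outside the mask, 1..n_bins inside."""

    levels: np.ndarray
    n_bins: int
    bounds: tuple[float, float]

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=np.int32)
        inside = self.levels[self.levels > 0]
        if inside.size and int(inside.max()) > self.n_bins:
            raise ValueError("levels exceed n_bins")

    @property
    def mask(self) -> np.ndarray:
        return self.levels > 0

    @property
    def n_masked(self) -> int:
        return int((self.levels > 0).sum())


def discretize(
    pmap: PolarMap,
    n_bins: int,
    bounds: tuple[float, float] | None = None,
) -> DiscretizedMap:
    """Discretize a polar map at the given bin depth.

    Parameters
    ----------
    pmap : PolarMap
        Peak-normalized uptake image with ROI mask.
    n_bins : int
        Number of gray levels. The standard depths are 8, 16, 32, 64 and
        128; other positive values are accepted with a warning.
    bounds : (min, max), optional
        Absolute resampling bounds. Default: the masked minimum/maximum
        (relative mode).
    """
    if n_bins < 1:
        raise ValueError("n_bins must be positive")
    if n_bins not in STANDARD_BIN_DEPTHS:
        warnings.warn(
            f"non-standard bin depth {n_bins}; standard depths are "
            f"{STANDARD_BIN_DEPTHS}",
            stacklevel=2,
        )
    mask = pmap.mask
    if not mask.any():
        raise ValueError("empty mask")
    u = pmap.pixels
    if bounds is None:
        lo, hi = float(u[mask].min()), float(u[mask].max())
    else:
        lo, hi = float(bounds[0]), float(bounds[1])
    levels = np.zeros(u.shape, dtype=np.int32)
    if hi <= lo:
        levels[mask] = 1
        return DiscretizedMap(levels=levels, n_bins=n_bins, bounds=(lo, hi))
    lv = 1 + np.floor(n_bins * (u[mask] - lo) / (hi - lo)).astype(np.int64)
    levels[mask] = np.clip(lv, 1, n_bins)
    return DiscretizedMap(levels=levels, n_bins=n_bins, bounds=(lo, hi))
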