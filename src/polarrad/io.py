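"""Polar-map image I/O.

A polar map is the 2D "bullseye" projection of the left-ventricular
myocardium used in nuclear cardiology to display relative tracer retention.
This module reads and writes the 8-bit single-channel lossless PNG
representation of such maps (256 gray levels), constructs the circular
whole-left-ventricle region of interest, and normalizes uptake so that the
peak value inside the region equals 100%.

Encoding convention: relative uptake ``u`` in percent of peak maps to the
byte ``round(u / 100 * 255)`` with round-half-up; background outside the
region of interest encodes as 0. Decoding maps byte ``v`` to
``v / 255 * 100`` and then rescales so the masked maximum is exactly 100.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from PIL import Image

#: Minimum number of pixels a valid region of interest must contain.
MIN_MASK_PIXELS = 64

#: One 8-bit quantization step on the percent-of-peak scale.
QUANTIZATION_STEP = 100.0 / 255.0


class PolarMapError(ValueError):
    """Raised for malformed polar-map images or regions of interest."""


@dataclass
class PolarMap:
    """A peak-normalized relative-uptake image with a circular ROI mask.

    Attributes
    ----------
    pixels : ndarray of float
        Relative uptake in percent of peak, in [0, 100]. Zero outside the
        region of interest.
    mask : ndarray of bool
        True inside the left-ventricular region of interest.
    source : str
        File path or generator provenance.
    """

    pixels: np.ndarray
    mask: np.ndarray
    source: str = "memory"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.pixels.ndim != 2 or self.pixels.shape != self.mask.shape:
            raise PolarMapError("pixels and mask must be 2D arrays of equal shape")
        n_masked = int(self.mask.sum())
        if n_masked < MIN_MASK_PIXELS:
            raise PolarMapError(
                f"region of interest has {n_masked} pixels; at least "
                f"{MIN_MASK_PIXELS} required"
            )
        peak = float(self.pixels[self.mask].max())
        if abs(peak - 100.0) > QUANTIZATION_STEP:
            raise PolarMapError(
                f"masked maximum is {peak:.4f}; maps must be peak-normalized to 100"
            )

    @classmethod
    def from_raw(cls, raw: np.ndarray, mask: np.ndarray, source: str = "memory") -> "PolarMap":
        """Build a map from raw non-negative values, normalizing peak to 100."""
        raw = np.asarray(raw, dtype=float)
        mask = np.asarray(mask, dtype=bool)
        if raw.shape != mask.shape:
            raise PolarMapError("raw and mask shapes differ")
        if not mask.any() or float(raw[mask].max()) <= 0:
            raise PolarMapError("region of interest is empty or all zero")
        pixels = np.zeros_like(raw)
        pixels[mask] = raw[mask] * (100.0 / raw[mask].max())
        return cls(pixels=pixels, mask=mask, source=source)

    @property
    def masked_values(self) -> np.ndarray:
        return self.pixels[self.mask]


def centered_disc_mask(shape: tuple[int, int], radius: float) -> np.ndarray:
    """Boolean mask of the centered disc of the given radius (inclusive)."""
    h, w = shape
    yy, xx = np.ogrid[:h, :w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    return np.hypot(yy - cy, xx - cx) <= radius


def derive_disc_mask(arr: np.ndarray) -> np.ndarray:
    """Maximal centered disc whose pixels are all strictly positive.

    The radius is the largest r such that every pixel at distance <= r from
    the image center has a positive value; with a dark background this
    recovers the polar-map disc exactly.
    """
    arr = np.asarray(arr)
    h, w = arr.shape
    yy, xx = np.ogrid[:h, :w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    dist = np.hypot(yy - cy, xx - cx)
    positive = arr > 0
    nonpos_dist = dist[~positive]
    if nonpos_dist.size == 0:
        radius = min(h - 1, w - 1) / 2.0
        return dist <= radius
    mask = dist < float(nonpos_dist.min())
    if not mask.any():
        raise PolarMapError("no positive region at the image center (empty map)")
    return mask


def encode_uptake(uptake: np.ndarray) -> np.ndarray:
    """Percent-of-peak -> byte with round-half-up (documented rounding rule)."""
    return np.clip(np.floor(np.asarray(uptake, dtype=float) / 100.0 * 255.0 + 0.5), 0, 255).astype(np.uint8)


def read_polar_png(path: str | os.PathLike, mask_path: str | os.PathLike | None = None) -> PolarMap:
    """Read an 8-bit single-channel polar-map PNG.

    Parameters
    ----------
    path : path-like
        The polar-map image; must be a single-channel 8-bit PNG.
    mask_path : path-like, optional
        Sidecar region-of-interest PNG (nonzero = inside). When absent the
        mask is the maximal centered disc of strictly positive pixels.
    """
    with Image.open(path) as im:
        if im.format != "PNG":
            raise PolarMapError(f"{path}: not a PNG file (format={im.format})")
        if im.mode != "L":
            raise PolarMapError(
                f"{path}: unsupported mode {im.mode!r}; single-channel 8-bit PNG required"
            )
        arr = np.asarray(im, dtype=np.uint8)
    if mask_path is not None:
        with Image.open(mask_path) as mim:
            if mim.mode != "L":
                raise PolarMapError(f"{mask_path}: mask must be single-channel 8-bit PNG")
            mask = np.asarray(mim) > 0
        if mask.shape != arr.shape:
            raise PolarMapError("mask shape does not match image shape")
    else:
        if not (arr > 0).any():
            raise PolarMapError(f"{path}: image is all zero (empty region)")
        mask = derive_disc_mask(arr)
    if not mask.any() or int(arr[mask].max()) == 0:
        raise PolarMapError(f"{path}: masked region is all zero (empty region)")
    uptake = arr.astype(float) / 255.0 * 100.0
    return PolarMap.from_raw(uptake, mask, source=str(path))


def write_polar_png(pmap: PolarMap, path: str | os.PathLike) -> None:
    """Write a polar map as a lossless 8-bit single-channel PNG."""
    data = np.zeros(pmap.pixels.shape, dtype=np.uint8)
    data[pmap.mask] = encode_uptake(pmap.pixels[pmap.mask])
    Image.fromarray(data, mode="L").save(path, format="PNG")
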