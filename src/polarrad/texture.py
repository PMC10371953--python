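"""Second-order texture matrices and their scalar features.

Four matrix families are computed from a discretized gray-level grid, all
in 2D with the four standard directions (0, 45, 90, 135 degrees) merged
into a single matrix before feature computation:

GLCM
    Symmetric co-occurrence counts of level pairs at distance 1.
GLRLM
    Counts of maximal straight runs of equal level, by level and length.
GLZLM
    Counts of 8-connected zones of equal level, by level and size
    (also known as the gray-level size-zone matrix).
NGLDM
    Dependence counts: for each pixel, the number of its 8-neighbours
    inside the mask sharing its level.

All matrices hold raw integer counts; features normalize internally.
Level index ``i`` runs 1..n_levels, and the second index (neighbour level,
run length, zone size, dependence count) is 1-based except for NGLDM
where dependence 0 is meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.feature import graycomatrix

#: Row/column offsets of the four 2D directions at distance 1.
DIRECTIONS_2D = ((0, 1), (-1, 1), (-1, 0), (-1, -1))


@dataclass
class TextureMatrix:
    """A texture count matrix plus the context needed by its features."""

    kind: str  # GLCM | GLRLM | NGLDM | GLZLM
    entries: np.ndarray  # integer counts
    n_levels: int
    n_pixels: int
    aggregation: str = "merged-4-directions"


def _require_mask(dmap) -> np.ndarray:
    mask = dmap.mask
    if not mask.any():
        raise ValueError("empty mask")
    return mask


# ---------------------------------------------------------------------------
# GLCM

def compute_glcm(dmap) -> TextureMatrix:
    """Merged symmetric co-occurrence matrix at distance 1.

    Pixels outside the mask carry level 0 and never co-occur: the level-0
    row and column are stripped after counting.
    """
    mask = _require_mask(dmap)
    if int(mask.sum()) < 2:
        raise ValueError("GLCM requires at least 2 masked pixels")
    lv = dmap.levels.astype(np.uint8 if dmap.n_bins <= 255 else np.int32)
    # skimage handles the four 2D angles; symmetric=True merges each
    # direction with its opposite.
    glcm = graycomatrix(
        lv,
        distances=[1],
        angles=[0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4],
        levels=dmap.n_bins + 1,
        symmetric=True,
    )
    merged = glcm[:, :, 0, :].sum(axis=2)[1:, 1:]
    return TextureMatrix("GLCM", merged.astype(np.int64), dmap.n_bins, dmap.n_masked)


def glcm_features(m: TextureMatrix) -> dict[str, float]:
    if m.kind != "GLCM":
        raise ValueError("expected a GLCM matrix")
    total = m.entries.sum()
    if total == 0:
        raise ValueError("GLCM has no co-occurrences")
    p = m.entries / total
    g = m.n_levels
    i = np.arange(1, g + 1)[:, None]
    j = np.arange(1, g + 1)[None, :]
    diff = i - j
    mu_i = float((i * p).sum())
    mu_j = float((j * p).sum())
    var_i = float(((i - mu_i) ** 2 * p).sum())
    var_j = float(((j - mu_j) ** 2 * p).sum())
    if var_i > 0 and var_j > 0:
        corr = float((((i - mu_i) * (j - mu_j) * p).sum()) / np.sqrt(var_i * var_j))
    else:
        corr = 0.0  # degenerate single-level region
    pos = p[p > 0]
    return {
        "GLCM_Homogeneity": float((p / (1.0 + np.abs(diff))).sum()),
        "GLCM_Energy": float((p**2).sum()),
        "GLCM_Contrast": float((p * diff**2).sum()),
        "GLCM_Correlation": corr,
        "GLCM_Entropy_log2": float(-(pos * np.log2(pos)).sum()),
        "GLCM_Entropy_log10": float(-(pos * np.log10(pos)).sum()),
        "GLCM_Dissimilarity": float((p * np.abs(diff)).sum()),
    }


# ---------------------------------------------------------------------------
# GLRLM

def _lines_for_direction(levels: np.ndarray, direction: tuple[int, int]) -> list[np.ndarray]:
    """The grid decomposed into 1D scan lines along one direction."""
    if direction == (0, 1):
        return list(levels)
    if direction == (-1, 0):
        return list(levels.T)
    h, w = levels.shape
    if direction == (-1, 1):  # 45 degrees: anti-diagonals
        flipped = levels[::-1]
        return [flipped.diagonal(k).copy() for k in range(-(h - 1), w)]
    if direction == (-1, -1):  # 135 degrees: main diagonals
        return [levels.diagonal(k).copy() for k in range(-(h - 1), w)]
    raise ValueError(f"unknown direction {direction}")


def _run_lengths(lines: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Run-length encode masked (level>0) segments of the given lines."""
    sep = np.zeros(1, dtype=np.int64)
    parts: list[np.ndarray] = []
    for ln in lines:
        parts.append(np.asarray(ln, dtype=np.int64))
        parts.append(sep)
    a = np.concatenate(parts) if parts else sep
    change = np.flatnonzero(np.diff(a) != 0) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [a.size]))
    vals = a[starts]
    lens = ends - starts
    keep = vals > 0
    return vals[keep], lens[keep]


def compute_glrlm(dmap) -> TextureMatrix:
    """Merged run-length matrix over the four 2D directions.

    A run is a maximal straight segment of equal level within the mask;
    entry (i, j) counts runs of level i and length j.
    """
    _require_mask(dmap)
    levels = dmap.levels
    max_len = max(levels.shape)
    counts = np.zeros((dmap.n_bins, max_len), dtype=np.int64)
    for direction in DIRECTIONS_2D:
        vals, lens = _run_lengths(_lines_for_direction(levels, direction))
        np.add.at(counts, (vals - 1, lens - 1), 1)
    return TextureMatrix("GLRLM", counts, dmap.n_bins, dmap.n_masked)


def glrlm_features(m: TextureMatrix) -> dict[str, float]:
    if m.kind != "GLRLM":
        raise ValueError("expected a GLRLM matrix")
    c = m.entries.astype(float)
    n_runs = c.sum()
    if n_runs == 0:
        raise ValueError("zero runs")
    i = np.arange(1, c.shape[0] + 1, dtype=float)[:, None]
    j = np.arange(1, c.shape[1] + 1, dtype=float)[None, :]
    row = c.sum(axis=1)
    col = c.sum(axis=0)
    return {
        "GLRLM_SRE": float((c / j**2).sum() / n_runs),
        "GLRLM_LRE": float((c * j**2).sum() / n_runs),
        "GLRLM_LGRE": float((c / i**2).sum() / n_runs),
        "GLRLM_HGRE": float((c * i**2).sum() / n_runs),
        "GLRLM_SRLGE": float((c / (i**2 * j**2)).sum() / n_runs),
        "GLRLM_SRHGE": float((c * i**2 / j**2).sum() / n_runs),
        "GLRLM_LRLGE": float((c * j**2 / i**2).sum() / n_runs),
        "GLRLM_LRHGE": float((c * i**2 * j**2).sum() / n_runs),
        "GLRLM_GLNU": float((row**2).sum() / n_runs),
        "GLRLM_RLNU": float((col**2).sum() / n_runs),
        # merged convention: pixel budget is n_pixels per direction
        "GLRLM_RP": float(n_runs / (m.n_pixels * len(DIRECTIONS_2D))),
    }


# ---------------------------------------------------------------------------
# GLZLM (size-zone)

_EIGHT_CONN = np.ones((3, 3), dtype=int)


def compute_glzlm(dmap) -> TextureMatrix:
    """Zone matrix: 8-connected components of equal level, by level and size."""
    _require_mask(dmap)
    levels = dmap.levels
    n_pix = dmap.n_masked
    counts = np.zeros((dmap.n_bins, n_pix), dtype=np.int64)
    for lvl in np.unique(levels[levels > 0]):
        lab, n_lab = ndimage.label(levels == lvl, structure=_EIGHT_CONN)
        if n_lab == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        np.add.at(counts, (int(lvl) - 1, sizes - 1), 1)
    return TextureMatrix("GLZLM", counts, dmap.n_bins, n_pix)


def glzlm_features(m: TextureMatrix) -> dict[str, float]:
    if m.kind != "GLZLM":
        raise ValueError("expected a GLZLM matrix")
    c = m.entries.astype(float)
    n_zones = c.sum()
    if n_zones == 0:
        raise ValueError("zero zones")
    i = np.arange(1, c.shape[0] + 1, dtype=float)[:, None]
    s = np.arange(1, c.shape[1] + 1, dtype=float)[None, :]
    row = c.sum(axis=1)
    col = c.sum(axis=0)
    return {
        "GLZLM_SZE": float((c / s**2).sum() / n_zones),
        "GLZLM_LZE": float((c * s**2).sum() / n_zones),
        "GLZLM_LGZE": float((c / i**2).sum() / n_zones),
        "GLZLM_HGZE": float((c * i**2).sum() / n_zones),
        "GLZLM_SZLGE": float((c / (i**2 * s**2)).sum() / n_zones),
        "GLZLM_SZHGE": float((c * i**2 / s**2).sum() / n_zones),
        "GLZLM_LZLGE": float((c * s**2 / i**2).sum() / n_zones),
        "GLZLM_LZHGE": float((c * i**2 * s**2).sum() / n_zones),
        "GLZLM_GLNU": float((row**2).sum() / n_zones),
        "GLZLM_ZLNU": float((col**2).sum() / n_zones),
        "GLZLM_ZP": float(n_zones / m.n_pixels),
    }


# ---------------------------------------------------------------------------
# NGLDM (dependence counts)

_NEIGHBOUR_OFFSETS = (
    (-1, -1), (-1, 0), (-1, 1),
    (0, -1), (0, 1),
    (1, -1), (1, 0), (1, 1),
)


def compute_ngldm(dmap) -> TextureMatrix:
    """Dependence matrix Q(i, k): masked pixels of level i with exactly k
    of their 8 in-mask neighbours sharing level i. Columns are k = 0..8."""
    mask = _require_mask(dmap)
    levels = dmap.levels
    h, w = levels.shape
    pad = np.zeros((h + 2, w + 2), dtype=levels.dtype)
    pad[1:-1, 1:-1] = levels
    dep = np.zeros((h, w), dtype=np.int64)
    for dy, dx in _NEIGHBOUR_OFFSETS:
        nb = pad[1 + dy : 1 + dy + h, 1 + dx : 1 + dx + w]
        dep += (nb == levels) & (nb > 0)
    counts = np.zeros((dmap.n_bins, 9), dtype=np.int64)
    np.add.at(counts, (levels[mask] - 1, dep[mask]), 1)
    return TextureMatrix("NGLDM", counts, dmap.n_bins, dmap.n_masked)


def ngldm_features(m: TextureMatrix) -> dict[str, float]:
    """Coarseness, contrast and busyness from the dependence matrix.

    Adapted from the Amadasun-King neighbourhood statistics: coarseness is
    the mean fraction of level-matching neighbour relations, contrast the
    normalized squared level spread of the marginal, and busyness the ratio
    of mean mismatch to the total level-probability imbalance.
    """
    if m.kind != "NGLDM":
        raise ValueError("expected an NGLDM matrix")
    q = m.entries.astype(float)
    total = q.sum()
    if total == 0:
        raise ValueError("empty dependence matrix")
    p = q / total
    k = np.arange(9, dtype=float)[None, :]
    levels = np.arange(1, q.shape[0] + 1, dtype=float)
    p_i = p.sum(axis=1)
    present = p_i > 0
    ng = int(present.sum())
    coarseness = float((p * k).sum() / 8.0)
    if ng > 1:
        pi = p_i[present][:, None]
        pj = p_i[present][None, :]
        li = levels[present][:, None]
        lj = levels[present][None, :]
        contrast = float((pi * pj * (li - lj) ** 2).sum() / (ng * (ng - 1)))
        ip = levels[present] * p_i[present]
        denom = float(np.abs(ip[:, None] - ip[None, :]).sum())
        mismatch = float((p * (8.0 - k)).sum() / 8.0)
        busyness = mismatch / denom if denom > 0 else 0.0
    else:
        contrast = 0.0
        busyness = 0.0
    return {
        "NGLDM_Coarseness": coarseness,
        "NGLDM_Contrast": contrast,
        "NGLDM_Busyness": busyness,
    }
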