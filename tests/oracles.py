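"""Naive brute-force texture-matrix oracles.

Independent of the package implementation: plain Python loops over cells,
used to verify the vectorized matrices on exhaustively enumerated and
randomly sampled small grids.
"""

import numpy as np

DIRECTIONS = ((0, 1), (-1, 1), (-1, 0), (-1, -1))


def oracle_glrlm(levels: np.ndarray, n_bins: int) -> np.ndarray:
    """Runs = maximal straight same-level segments inside the mask."""
    levels = np.asarray(levels)
    h, w = levels.shape
    max_len = max(h, w)
    counts = np.zeros((n_bins, max_len), dtype=np.int64)

    def inside(y, x):
        return 0 <= y < h and 0 <= x < w and levels[y, x] > 0

    for dy, dx in DIRECTIONS:
        for y in range(h):
            for x in range(w):
                if not inside(y, x):
                    continue
                lvl = levels[y, x]
                # only start of a run counts
                if inside(y - dy, x - dx) and levels[y - dy, x - dx] == lvl:
                    continue
                length = 1
                ny, nx = y + dy, x + dx
                while inside(ny, nx) and levels[ny, nx] == lvl:
                    length += 1
                    ny += dy
                    nx += dx
                counts[lvl - 1, length - 1] += 1
    return counts


def oracle_glzlm(levels: np.ndarray, n_bins: int) -> np.ndarray:
    """Zones = 8-connected components of equal level, via BFS flood fill."""
    levels = np.asarray(levels)
    h, w = levels.shape
    n_pix = int((levels > 0).sum())
    counts = np.zeros((n_bins, max(n_pix, 1)), dtype=np.int64)
    seen = np.zeros_like(levels, dtype=bool)
    for y in range(h):
        for x in range(w):
            if levels[y, x] <= 0 or seen[y, x]:
                continue
            lvl = levels[y, x]
            stack = [(y, x)]
            seen[y, x] = True
            size = 0
            while stack:
                cy, cx = stack.pop()
                size += 1
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        ny, nx = cy + dy, cx + dx
                        if (
                            0 <= ny < h and 0 <= nx < w
                            and not seen[ny, nx] and levels[ny, nx] == lvl
                        ):
                            seen[ny, nx] = True
                            stack.append((ny, nx))
            counts[lvl - 1, size - 1] += 1
    return counts


def oracle_glcm(levels: np.ndarray, n_bins: int) -> np.ndarray:
    """Symmetric distance-1 co-occurrences over the four directions."""
    levels = np.asarray(levels)
    h, w = levels.shape
    counts = np.zeros((n_bins, n_bins), dtype=np.int64)
    for dy, dx in DIRECTIONS:
        for y in range(h):
            for x in range(w):
                ny, nx = y + dy, x + dx
                if not (0 <= ny < h and 0 <= nx < w):
                    continue
                a, b = levels[y, x], levels[ny, nx]
                if a > 0 and b > 0:
                    counts[a - 1, b - 1] += 1
                    counts[b - 1, a - 1] += 1
    return counts


def oracle_ngldm(levels: np.ndarray, n_bins: int) -> np.ndarray:
    """Dependence counts: equal-level in-mask 8-neighbours per pixel."""
    levels = np.asarray(levels)
    h, w = levels.shape
    counts = np.zeros((n_bins, 9), dtype=np.int64)
    for y in range(h):
        for x in range(w):
            lvl = levels[y, x]
            if lvl <= 0:
                continue
            dep = 0
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    if dy == 0 and dx == 0:
                        continue
                    ny, nx = y + dy, x + dx
                    if 0 <= ny < h and 0 <= nx < w and levels[ny, nx] == lvl:
                        dep += 1
            counts[lvl - 1, dep] += 1
    return counts
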