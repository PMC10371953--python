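import itertools

import numpy as np
import pytest

from polarrad.discretize import discretize
from polarrad.texture import (
    TextureMatrix,
    compute_glcm,
    compute_glrlm,
    compute_glzlm,
    compute_ngldm,
    glcm_features,
    glrlm_features,
    glzlm_features,
    ngldm_features,
)

from conftest import disc_map, dmap_from_levels
from oracles import oracle_glcm, oracle_glrlm, oracle_glzlm, oracle_ngldm


class TestGLRLMMatrix:
    def test_constant_3x3_square_has_16_merged_runs(self):
        dmap = dmap_from_levels(np.ones((3, 3), dtype=int))
        m = compute_glrlm(dmap)
        assert m.entries.sum() == 16  # 3 + 3 horizontal/vertical, 5 + 5 diagonal
        # diagonal runs of lengths 1, 2, 3, 2, 1 in each diagonal direction
        assert m.entries[0, 2] == 3 + 3 + 1 + 1
        assert m.entries[0, 1] == 4
        assert m.entries[0, 0] == 4

    def test_checkerboard_horizontal_runs_all_length_one(self):
        levels = np.indices((4, 4)).sum(axis=0) % 2 + 1
        vals, lens = _runs_one_direction(levels, (0, 1))
        assert (lens == 1).all()
        assert len(lens) == 16
        assert (vals == 1).sum() == (vals == 2).sum() == 8

    def test_single_pixel_one_run_per_direction(self):
        levels = np.zeros((3, 3), dtype=int)
        levels[1, 1] = 2
        m = compute_glrlm(dmap_from_levels(levels))
        assert m.entries.sum() == 4
        assert m.entries[1, 0] == 4

    def test_per_direction_pixel_conservation(self):
        rng = np.random.default_rng(3)
        levels = rng.integers(0, 4, size=(9, 9))
        n_pix = int((levels > 0).sum())
        for d in ((0, 1), (-1, 1), (-1, 0), (-1, -1)):
            vals, lens = _runs_one_direction(levels, d)
            assert lens.sum() == n_pix


def _runs_one_direction(levels, direction):
    from polarrad.texture import _lines_for_direction, _run_lengths

    return _run_lengths(_lines_for_direction(np.asarray(levels, dtype=np.int64), direction))


class TestGLRLMFeatures:
    def test_glnu_equals_run_count_for_single_level(self):
        m = compute_glrlm(dmap_from_levels(np.ones((3, 3), dtype=int)))
        f = glrlm_features(m)
        assert f["GLRLM_GLNU"] == pytest.approx(m.entries.sum())

    def test_glnu_worked_example_three_one_split(self):
        """Runs split 3 vs 1 across two levels: GLNU = (9+1)/4 = 2.5."""
        entries = np.zeros((2, 4), dtype=np.int64)
        entries[0, 0] = 3
        entries[1, 1] = 1
        m = TextureMatrix("GLRLM", entries, n_levels=2, n_pixels=5)
        assert glrlm_features(m)["GLRLM_GLNU"] == pytest.approx(2.5)

    def test_glnu_invariant_under_level_permutation(self):
        rng = np.random.default_rng(0)
        entries = rng.integers(0, 5, size=(3, 4))
        base = glrlm_features(TextureMatrix("GLRLM", entries, 3, 20))["GLRLM_GLNU"]
        for perm in itertools.permutations(range(3)):
            m = TextureMatrix("GLRLM", entries[list(perm)], 3, 20)
            assert glrlm_features(m)["GLRLM_GLNU"] == pytest.approx(base)

    def test_rp_uses_pixels_times_directions(self):
        dmap = dmap_from_levels(np.ones((3, 3), dtype=int))
        f = glrlm_features(compute_glrlm(dmap))
        assert f["GLRLM_RP"] == pytest.approx(16 / (9 * 4))


class TestGLZLM:
    def test_constant_disc_single_zone(self, constant_disc):
        dmap = discretize(constant_disc, 16)
        m = compute_glzlm(dmap)
        f = glzlm_features(m)
        assert m.entries.sum() == 1
        assert f["GLZLM_GLNU"] == pytest.approx(1.0)
        assert f["GLZLM_ZP"] == pytest.approx(1.0 / dmap.n_masked)

    def test_two_blobs_of_different_levels(self):
        levels = np.zeros((6, 6), dtype=int)
        levels[0:2, 0:2] = 1
        levels[4:6, 4:6] = 2
        m = compute_glzlm(dmap_from_levels(levels))
        assert m.entries.sum() == 2
        f = glzlm_features(m)
        assert f["GLZLM_GLNU"] == pytest.approx(1.0)
        assert m.entries[0, 3] == 1 and m.entries[1, 3] == 1

    def test_checkerboard_matches_connected_components_oracle(self):
        levels = (np.indices((5, 5)).sum(axis=0) % 2 + 1).astype(int)
        m = compute_glzlm(dmap_from_levels(levels))
        assert np.array_equal(m.entries, oracle_glzlm(levels, 3))
        # 8-connectivity joins each colour diagonally into one zone
        assert m.entries.sum() == 2

    def test_zone_pixel_conservation(self):
        rng = np.random.default_rng(5)
        levels = rng.integers(0, 4, size=(8, 8))
        m = compute_glzlm(dmap_from_levels(levels))
        s = np.arange(1, m.entries.shape[1] + 1)
        assert (m.entries * s).sum() == (levels > 0).sum()


class TestGLCM:
    def test_constant_region_degenerate_features(self, constant_disc):
        dmap = discretize(constant_disc, 16)
        f = glcm_features(compute_glcm(dmap))
        assert f["GLCM_Contrast"] == pytest.approx(0.0)
        assert f["GLCM_Homogeneity"] == pytest.approx(1.0)
        assert f["GLCM_Energy"] == pytest.approx(1.0)

    def test_vertical_stripes_contrast_horizontal_direction(self):
        """Two-level stripes: every 0-degree co-occurrence crosses levels."""
        levels = np.tile([1, 2, 1, 2], (2, 1))
        counts = oracle_glcm_one_direction(levels, (0, 1))
        p = counts / counts.sum()
        i = np.arange(1, 3)[:, None]
        j = np.arange(1, 3)[None, :]
        contrast = (p * (i - j) ** 2).sum()
        assert contrast == pytest.approx(1.0)  # (delta level)^2 = 1

    def test_correlation_invariant_to_level_shift(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            levels = rng.integers(1, 4, size=(6, 6))
            m1 = compute_glcm(dmap_from_levels(levels, n_bins=8))
            m2 = compute_glcm(dmap_from_levels(levels + 2, n_bins=8))
            c1 = glcm_features(m1)["GLCM_Correlation"]
            c2 = glcm_features(m2)["GLCM_Correlation"]
            assert c1 == pytest.approx(c2, abs=1e-12)

    def test_fewer_than_two_masked_pixels_rejected(self):
        levels = np.zeros((3, 3), dtype=int)
        levels[1, 1] = 1
        with pytest.raises(ValueError):
            compute_glcm(dmap_from_levels(levels))


def oracle_glcm_one_direction(levels, direction):
    h, w = levels.shape
    g = int(levels.max())
    counts = np.zeros((g, g), dtype=int)
    dy, dx = direction
    for y in range(h):
        for x in range(w):
            ny, nx = y + dy, x + dx
            if 0 <= ny < h and 0 <= nx < w and levels[y, x] > 0 and levels[ny, nx] > 0:
                counts[levels[y, x] - 1, levels[ny, nx] - 1] += 1
                counts[levels[ny, nx] - 1, levels[y, x] - 1] += 1
    return counts


class TestNGLDM:
    def test_constant_disc_interior_dependence_eight(self, constant_disc):
        dmap = discretize(constant_disc, 16)
        m = compute_ngldm(dmap)
        # interior pixels (all 8 neighbours inside) dominate
        assert m.entries[0, 8] > 0
        assert m.entries.sum() == dmap.n_masked

    def test_single_pixel_dependence_zero(self):
        levels = np.zeros((3, 3), dtype=int)
        levels[1, 1] = 1
        m = compute_ngldm(dmap_from_levels(levels))
        assert m.entries[0, 0] == 1
        assert m.entries.sum() == 1

    def test_small_pattern_matches_neighbour_enumeration(self):
        levels = np.array([[1, 2, 1], [2, 1, 2], [1, 2, 1]])
        m = compute_ngldm(dmap_from_levels(levels))
        assert np.array_equal(m.entries, oracle_ngldm(levels, 3))


class TestRotationInvariance:
    def test_all_texture_features_invariant_under_90_degree_rotation(self):
        rng = np.random.default_rng(11)
        levels = rng.integers(0, 4, size=(7, 7))
        levels[3, 3] = 1
        rot = np.rot90(levels)
        for compute, feats in [
            (compute_glcm, glcm_features),
            (compute_glrlm, glrlm_features),
            (compute_glzlm, glzlm_features),
            (compute_ngldm, ngldm_features),
        ]:
            f1 = feats(compute(dmap_from_levels(levels)))
            f2 = feats(compute(dmap_from_levels(rot)))
            for k in f1:
                assert f1[k] == pytest.approx(f2[k], rel=1e-12), k


def test_oracle_equivalence_spot_checks():
    rng = np.random.default_rng(21)
    for _ in range(20):
        levels = rng.integers(0, 4, size=rng.integers(2, 5, size=2))
        if (levels > 0).sum() == 0:
            continue
        dmap = dmap_from_levels(levels)
        assert np.array_equal(compute_glrlm(dmap).entries, oracle_glrlm(levels, 3))
        assert np.array_equal(compute_glzlm(dmap).entries, oracle_glzlm(levels, 3))
        assert np.array_equal(compute_ngldm(dmap).entries, oracle_ngldm(levels, 3))
        if (levels > 0).sum() >= 2:
            assert np.array_equal(compute_glcm(dmap).entries, oracle_glcm(levels, 3))
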