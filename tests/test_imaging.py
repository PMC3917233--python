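"""Imaging: stitching, preprocessing, binarization, morphology, watershed."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from quanthisto import imaging
from quanthisto.imaging import (LabelMap, SectionImage, binarize_adaptive,
                                morph_clean, preprocess,
                                segmentation_error_rate, stitch_tiles,
                                watershed_segment)


def _img(arr, **kw):
    return SectionImage(np.asarray(arr), **kw)


class TestStitch:
    def test_grid_dimensions(self):
        tiles = [np.full((64, 64), i, dtype=np.uint8) for i in range(9)]
        out = stitch_tiles(tiles, {"rows": 3, "cols": 3, "tile_px": 64})
        assert out.pixels.shape == (192, 192)
        # row-major placement, tiles abut exactly
        assert out.pixels[0, 0] == 0 and out.pixels[0, 191] == 2
        assert out.pixels[191, 191] == 8

    def test_identity_single_tile(self):
        tile = np.arange(16, dtype=np.uint8).reshape(4, 4)
        out = stitch_tiles([tile], {"rows": 1, "cols": 1, "tile_px": 4})
        assert np.array_equal(out.pixels, tile)

    def test_missing_tile_names_position(self):
        tiles = [np.zeros((8, 8))] * 3
        with pytest.raises(ValueError, match=r"row=1, col=1"):
            stitch_tiles(tiles, {"rows": 2, "cols": 2, "tile_px": 8})

    def test_shape_mismatch_rejected(self):
        tiles = [np.zeros((8, 8)), np.zeros((8, 9))]
        with pytest.raises(ValueError, match="shape"):
            stitch_tiles(tiles, {"rows": 1, "cols": 2, "tile_px": 8})


class TestPreprocess:
    def test_identity(self):
        arr = np.random.default_rng(0).integers(0, 255, (32, 32), dtype=np.uint8)
        out = preprocess(_img(arr), gamma=1, contrast=1, brightness=0)
        assert np.array_equal(out.pixels, arr)

    def test_gamma_closed_form(self):
        # normalized v under gamma 2 -> v**2 before contrast/brightness
        arr = np.full((8, 8), 64, dtype=np.uint8)
        out = preprocess(_img(arr), gamma=2.0)
        expect = np.floor((64 / 255) ** 2 * 255)
        assert np.allclose(out.pixels, expect)

    def test_constant_stays_constant(self):
        arr = np.full((8, 8), 120, dtype=np.uint8)
        out = preprocess(_img(arr), gamma=1.7, contrast=1.2, brightness=-0.1)
        assert len(np.unique(out.pixels)) == 1

    def test_bad_gamma(self):
        with pytest.raises(ValueError):
            preprocess(_img(np.zeros((4, 4))), gamma=0)


class TestBinarize:
    def test_uniform_image_empty_foreground(self):
        img = _img(np.full((64, 64), 200, dtype=np.uint8))
        assert not binarize_adaptive(img, window_px=15, offset=5).any()

    def test_dark_grid_recovered(self):
        # dark 2-px grid lines on a light field: >=99% pixel agreement
        arr = np.full((128, 128), 200, dtype=np.uint8)
        walls = np.zeros((128, 128), dtype=bool)
        for k in range(0, 128, 16):
            walls[k:k + 2, :] = True
            walls[:, k:k + 2] = True
        arr[walls] = 60
        got = binarize_adaptive(_img(arr), window_px=15, offset=10)
        agreement = (got == walls).mean()
        assert agreement >= 0.99

    def test_negative_max_offset_all_foreground(self):
        arr = np.random.default_rng(0).integers(0, 255, (32, 32), dtype=np.uint8)
        got = binarize_adaptive(_img(arr), window_px=9, offset=-300.0)
        assert got.all()

    def test_window_validation(self):
        img = _img(np.zeros((32, 32), dtype=np.uint8))
        with pytest.raises(ValueError):
            binarize_adaptive(img, window_px=10)
        with pytest.raises(ValueError):
            binarize_adaptive(img, window_px=65)


def brute_force_binary_morphology(mask, selem, op):
    """Pixel-by-pixel erosion/dilation oracle."""
    h, w = mask.shape
    r = selem.shape[0] // 2
    out = np.zeros_like(mask)
    for y in range(h):
        for x in range(w):
            vals = []
            for dy in range(-r, r + 1):
                for dx in range(-r, r + 1):
                    if not selem[dy + r, dx + r]:
                        continue
                    yy, xx = y + dy, x + dx
                    inside = 0 <= yy < h and 0 <= xx < w
                    vals.append(mask[yy, xx] if inside else False)
            out[y, x] = all(vals) if op == "erode" else any(vals)
    return out


class TestMorphClean:
    def test_isolated_pixel_removed(self):
        mask = np.zeros((16, 16), dtype=bool)
        mask[8, 8] = True
        assert not morph_clean(mask).any()

    def test_matches_brute_force_oracle(self):
        from skimage.morphology import disk
        rng = np.random.default_rng(5)
        selem = disk(1)
        for _ in range(5):
            mask = rng.random((10, 10)) < 0.45
            expect = mask
            for _ in range(2):
                expect = brute_force_binary_morphology(expect, selem, "erode")
            expect = brute_force_binary_morphology(expect, selem, "dilate")
            got = morph_clean(mask, n_erosions=2, n_dilations=1, selem_radius=1)
            assert np.array_equal(got, expect)

    def test_empty_mask(self):
        assert not morph_clean(np.zeros((8, 8), dtype=bool)).any()


class TestWatershed:
    def test_two_discs_two_labels(self):
        walls = np.ones((64, 64), dtype=bool)
        yy, xx = np.mgrid[0:64, 0:64]
        walls[(xx - 18) ** 2 + (yy - 32) ** 2 < 100] = False
        walls[(xx - 46) ** 2 + (yy - 32) ** 2 < 100] = False
        lm = watershed_segment(_img(np.zeros((64, 64), dtype=np.uint8)), walls,
                               min_cell_px=10)
        assert lm.n_cells == 2

    def test_matches_connected_components_for_separated_lumina(self):
        # two lumina separated by a 2-px wall
        walls = np.ones((40, 60), dtype=bool)
        walls[8:32, 6:28] = False
        walls[8:32, 30:52] = False   # 2-px wall at columns 28:30
        lm = watershed_segment(_img(np.zeros((40, 60), dtype=np.uint8)), walls,
                               min_cell_px=10)
        cc, ncc = ndi.label(~walls)
        assert lm.n_cells == ncc == 2
        # identical partition up to label permutation
        for i in range(1, ncc + 1):
            ids = np.unique(lm.labels[cc == i])
            assert len(ids) == 1 and ids[0] > 0

    def test_partition_property(self, small_section):
        """Every non-wall pixel receives exactly one label."""
        image, _, _ = small_section
        pre = preprocess(image)
        walls = morph_clean(binarize_adaptive(pre, 51, 10))
        lm = watershed_segment(image, walls, min_cell_px=0)
        assert (lm.labels[~walls] > 0).all()
        assert (lm.labels[walls] == 0).all()

    def test_all_foreground_warns_zero_cells(self):
        with pytest.warns(imaging.SegmentationWarning):
            lm = watershed_segment(_img(np.zeros((16, 16), dtype=np.uint8)),
                                   np.ones((16, 16), dtype=bool))
        assert lm.n_cells == 0


class TestErrorRate:
    def _truth(self):
        t = np.zeros((20, 40), dtype=np.int32)
        t[2:18, 2:18] = 1
        t[2:18, 22:38] = 2
        return LabelMap(t)

    def test_identity_is_zero(self):
        truth = self._truth()
        rate, mis = segmentation_error_rate(truth, truth)
        assert rate == 0.0 and len(mis) == 0

    def test_merge_counts_both_cells(self):
        truth = self._truth()
        merged = np.where(truth.labels > 0, 1, 0).astype(np.int32)
        rate, mis = segmentation_error_rate(LabelMap(merged), truth)
        assert rate == 1.0
        assert set(mis) == {1, 2}

    def test_monotone_under_merging(self, small_section):
        _, truth, _ = small_section
        lbl = truth.label_map.labels.copy()
        base_rate, _ = segmentation_error_rate(LabelMap(lbl, 0.7),
                                               truth.label_map)
        # merge two adjacent cells
        ids = truth.label_map.cell_ids
        lbl2 = lbl.copy()
        lbl2[lbl2 == ids[1]] = ids[0]
        rate2, _ = segmentation_error_rate(LabelMap(lbl2, 0.7),
                                           truth.label_map)
        assert rate2 >= base_rate

    def test_empty_truth_rejected(self):
        empty = LabelMap(np.zeros((8, 8), dtype=np.int32))
        with pytest.raises(ValueError):
            segmentation_error_rate(empty, empty)
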