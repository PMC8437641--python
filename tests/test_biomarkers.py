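import numpy as np
import pytest

from cscrseg import (ROIBox, binarize_sparse_map, extract_regions,
                     restore_to_full_frame)


class TestBinarize:
    def test_all_zero_map(self):
        assert not binarize_sparse_map(np.zeros((20, 20))).any()

    def test_nonzero_rule_is_support(self):
        S = np.zeros((20, 20))
        S[5:8, 5:8] = 1.0
        mask = binarize_sparse_map(S, rule="nonzero")
        np.testing.assert_array_equal(mask, S > 0)

    def test_adaptive_rule_keeps_bump_peak(self):
        r = np.arange(40)[:, None]
        c = np.arange(40)[None, :]
        S = np.exp(-((r - 20) ** 2 + (c - 20) ** 2) / (2 * 4.0 ** 2))
        mask = binarize_sparse_map(S, rule="adaptive")
        assert mask[20, 20]
        from scipy import ndimage
        _, n = ndimage.label(mask, structure=np.ones((3, 3), bool))
        assert n == 1

    def test_negative_entries_rejected(self):
        S = np.zeros((5, 5))
        S[0, 0] = -0.1
        with pytest.raises(ValueError):
            binarize_sparse_map(S)

    def test_unknown_rule(self):
        with pytest.raises(ValueError):
            binarize_sparse_map(np.zeros((5, 5)), rule="magic")


def _mask_with(areas_at):
    mask = np.zeros((60, 60), dtype=bool)
    for (r, c), side in areas_at:
        mask[r:r + side, c:c + side] = True
    return mask


class TestExtractRegions:
    def test_sorted_by_area_descending(self):
        # areas 40 < 4 px blocks: use 7x7=49 and 4x3=12
        mask = np.zeros((60, 60), dtype=bool)
        mask[2:9, 2:9] = True          # 49 px
        mask[30:34, 30:33] = True      # 12 px
        bset = extract_regions(mask, min_area=5)
        assert [r.area_px for r in bset.regions] == [49, 12]
        assert [r.label for r in bset.regions] == [1, 2]

    def test_min_area_drop(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[5, 5:8] = True            # 3 px line
        bset = extract_regions(mask, min_area=5)
        assert len(bset) == 0
        assert not bset.S_P.any()

    def test_max_regions_cap(self):
        mask = _mask_with([((i * 9, i * 9), 3) for i in range(6)])
        bset = extract_regions(mask, min_area=5, max_regions=3)
        assert len(bset) == 3

    def test_tie_break_topmost_leftmost(self):
        mask = _mask_with([((40, 2), 3), ((2, 40), 3)])  # equal 9-px areas
        bset = extract_regions(mask, min_area=5)
        assert bset.regions[0].centroid[0] < bset.regions[1].centroid[0]

    def test_idempotent_reextraction(self):
        rng = np.random.default_rng(0)
        mask = rng.random((80, 80)) > 0.92
        bset = extract_regions(mask, min_area=5)
        again = extract_regions(bset.S_P, min_area=5)
        assert [r.area_px for r in again.regions] == \
            [r.area_px for r in bset.regions]
        np.testing.assert_array_equal(again.S_P, bset.S_P)

    def test_single_component_masks(self):
        rng = np.random.default_rng(1)
        mask = rng.random((50, 50)) > 0.9
        from scipy import ndimage
        for reg in extract_regions(mask, min_area=1).regions:
            _, n = ndimage.label(reg.mask_roi, structure=np.ones((3, 3),
                                                                 bool))
            assert n == 1


class TestRestore:
    def _bset(self, box):
        mask = np.zeros((box.height, box.width), dtype=bool)
        mask[4:7, 4:7] = True
        return extract_regions(mask, min_area=5, box=box)

    def test_origin_box_pads_with_zeros(self):
        box = ROIBox(0, 0, 50, 50)
        bset = restore_to_full_frame(self._bset(box), (100, 100))
        np.testing.assert_array_equal(bset.full_mask[:50, :50], bset.S_P)
        assert not bset.full_mask[50:, :].any()
        assert not bset.full_mask[:, 50:].any()

    def test_centroid_translation(self):
        box = ROIBox(100, 100, 160, 160)
        bset = restore_to_full_frame(self._bset(box), (300, 300))
        roi_centroid = bset.regions[0].centroid
        full_centroid = bset.full_regions[0].centroid
        assert full_centroid == (roi_centroid[0] + 100, roi_centroid[1] + 100)

    def test_pixel_count_conserved(self):
        box = ROIBox(10, 20, 70, 90)
        bset = restore_to_full_frame(self._bset(box), (200, 200))
        assert bset.full_mask.sum() == bset.S_P.sum()

    def test_empty_regions_zero_mask(self):
        box = ROIBox(0, 0, 50, 50)
        bset = extract_regions(np.zeros((50, 50), bool), box=box)
        restored = restore_to_full_frame(bset, (80, 80))
        assert not restored.full_mask.any()

    def test_box_exceeding_frame_rejected(self):
        box = ROIBox(0, 0, 50, 50)
        with pytest.raises(ValueError):
            restore_to_full_frame(self._bset(box), (40, 40))
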