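from collections import deque

import numpy as np
import pytest

from cariesseg.core import Radiograph, SegmentationMask, ShapeMismatchError
from cariesseg.ccs import (
    ccs_sample_dataset,
    ccs_sample_pair,
    find_components,
    make_crop_window,
)


def flood_fill_components(mask: np.ndarray):
    """Independent BFS oracle for 8-connected components."""
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    h, w = mask.shape
    for r in range(h):
        for c in range(w):
            if mask[r, c] and not seen[r, c]:
                queue, members = deque([(r, c)]), []
                seen[r, c] = True
                while queue:
                    rr, cc = queue.popleft()
                    members.append((rr, cc))
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            nr, nc = rr + dr, cc + dc
                            if (0 <= nr < h and 0 <= nc < w
                                    and mask[nr, nc] and not seen[nr, nc]):
                                seen[nr, nc] = True
                                queue.append((nr, nc))
                comps.append(frozenset(members))
    return set(comps)


class TestFindComponents:
    def test_empty_mask(self):
        assert find_components(SegmentationMask(np.zeros((5, 5), np.uint8))) == []

    def test_single_square(self):
        m = np.zeros((8, 8), np.uint8)
        m[2:5, 2:5] = 1
        (comp,) = find_components(SegmentationMask(m))
        assert comp.area == 9
        assert comp.centroid == (3.0, 3.0)
        assert comp.bbox == (2, 2, 4, 4)

    def test_diagonal_pixels_are_one_component(self):
        m = np.zeros((4, 4), np.uint8)
        m[0, 0] = m[1, 1] = 1
        comps = find_components(SegmentationMask(m))
        assert len(comps) == 1
        assert comps[0].area == 2

    def test_matches_flood_fill_oracle_on_random_masks(self, rng):
        for _ in range(50):
            h, w = rng.integers(2, 17, size=2)
            m = (rng.random((h, w)) < 0.35).astype(np.uint8)
            got = {frozenset(c.pixels) for c in find_components(SegmentationMask(m))}
            assert got == flood_fill_components(m)

    def test_sorted_by_bbox_origin(self, rng):
        m = np.zeros((20, 20), np.uint8)
        m[15, 15] = 1
        m[2, 8] = 1
        m[2, 1] = 1
        comps = find_components(SegmentationMask(m))
        assert [c.bbox[:2] for c in comps] == [(2, 1), (2, 8), (15, 15)]


class TestMakeCropWindow:
    def test_centred_window(self):
        win = make_crop_window((5.0, 5.0), 4, (10, 10))
        assert (win.row0, win.col0, win.height, win.width) == (3, 3, 4, 4)

    def test_corner_clamp(self):
        win = make_crop_window((0.0, 0.0), 4, (10, 10))
        assert (win.row0, win.col0) == (0, 0)
        assert win.contains(0, 0)

    def test_oversized_crop_covers_frame(self):
        win = make_crop_window((4.0, 4.0), 64, (10, 10))
        assert (win.row0, win.col0, win.height, win.width) == (0, 0, 10, 10)

    def test_window_always_in_frame_and_contains_centroid(self, rng):
        for _ in range(200):
            h, w = rng.integers(3, 40, size=2)
            crop = int(rng.integers(1, 50))
            cr = rng.uniform(0, h - 1)
            cc = rng.uniform(0, w - 1)
            win = make_crop_window((cr, cc), crop, (h, w))
            assert 0 <= win.row0 and win.row0 + win.height <= h
            assert 0 <= win.col0 and win.col0 + win.width <= w
            assert win.contains(int(np.floor(cr + 0.5)), int(np.floor(cc + 0.5)))


def _pair_from_mask(m: np.ndarray, id="img"):
    img = Radiograph(id, np.full(m.shape, 0.5))
    return img, SegmentationMask(m)


class TestCcsSamplePair:
    def test_empty_mask_empty_list(self):
        img, msk = _pair_from_mask(np.zeros((20, 20), np.uint8))
        assert ccs_sample_pair(img, msk, 8) == []

    def test_small_lesion_exact_crop(self):
        m = np.zeros((300, 300), np.uint8)
        m[100:103, 200:203] = 1
        img, msk = _pair_from_mask(m)
        (crop,) = ccs_sample_pair(img, msk, 10)
        assert crop.image.shape == (10, 10) == crop.mask.shape
        assert crop.mask.sum() == 9

    def test_two_lesions_two_complete_crops(self):
        m = np.zeros((64, 64), np.uint8)
        m[5:8, 5:8] = 1
        m[40:44, 50:53] = 1
        img, msk = _pair_from_mask(m)
        crops = ccs_sample_pair(img, msk, 16)
        assert len(crops) == 2
        assert sum(c.mask.sum() for c in crops) == m.sum()

    def test_component_larger_than_crop_enlarges_window(self):
        m = np.zeros((64, 64), np.uint8)
        m[10:40, 20:26] = 1  # 30 px tall, crop_size 16
        img, msk = _pair_from_mask(m)
        (crop,) = ccs_sample_pair(img, msk, 16)
        assert crop.mask.sum() == m.sum()  # nothing lost
        assert crop.image.shape[0] >= 30

    def test_shape_mismatch_raises(self):
        img = Radiograph("a", np.full((10, 10), 0.5))
        msk = SegmentationMask(np.zeros((8, 8), np.uint8))
        with pytest.raises(ShapeMismatchError):
            ccs_sample_pair(img, msk, 8)

    def test_no_foreground_lost_on_synthetic_masks(self, default_synthetic_dataset):
        """Every source foreground pixel lands in at least one crop mask."""
        for img, msk in default_synthetic_dataset:
            crops = ccs_sample_pair(img, msk, 32)
            covered = np.zeros_like(msk.pixels, dtype=bool)
            for c in crops:
                win = c.window
                covered[win.row_slice, win.col_slice] |= c.mask.astype(bool)
            assert np.array_equal(covered, msk.pixels.astype(bool))

    def test_min_area_filter(self):
        m = np.zeros((32, 32), np.uint8)
        m[2, 2] = 1
        m[20:23, 20:23] = 1
        img, msk = _pair_from_mask(m)
        assert len(ccs_sample_pair(img, msk, 8, min_area=2)) == 1
        assert len(ccs_sample_pair(img, msk, 8, min_area=1)) == 2


class TestCcsSampleDataset:
    def test_counts_and_order(self):
        masks = [np.zeros((30, 30), np.uint8) for _ in range(3)]
        masks[0][5:7, 5:7] = 1
        masks[2][3:5, 3:5] = 1
        masks[2][20:22, 20:22] = 1
        pairs = [_pair_from_mask(m, id=f"i{k}") for k, m in enumerate(masks)]
        crops = ccs_sample_dataset(pairs, 8)
        assert len(crops) == 3
        assert [c.source_id for c in crops] == ["i0", "i2", "i2"]

    def test_size_reduction_vs_full_frames(self, default_synthetic_dataset):
        crops = ccs_sample_dataset(default_synthetic_dataset, 10)
        cropped_px = sum(c.image.size for c in crops)
        full_px = sum(img.pixels.size for img, _ in default_synthetic_dataset)
        # windows are 10x10 unless a lesion box forces a larger side
        for c in crops:
            rows, cols = np.nonzero(c.mask)
            box = max(rows.max() - rows.min(), cols.max() - cols.min()) + 1
            assert max(c.image.shape) <= max(10, box + 4)
        assert cropped_px / full_px < 0.005  # >=99.5% size reduction

    def test_rerun_identical(self, default_synthetic_dataset):
        a = ccs_sample_dataset(default_synthetic_dataset, 32)
        b = ccs_sample_dataset(default_synthetic_dataset, 32)
        assert len(a) == len(b)
        for ca, cb in zip(a, b):
            assert ca.window == cb.window
            assert np.array_equal(ca.image, cb.image)

    def test_crop_imbalance_gain(self, default_synthetic_dataset):
        """Mean crop foreground fraction >= 10x the full-frame fraction."""
        crops = ccs_sample_dataset(default_synthetic_dataset, 32)
        crop_frac = np.mean([c.mask.mean() for c in crops])
        full_frac = np.mean([m.foreground_fraction for _, m in default_synthetic_dataset])
        assert crop_frac >= 10 * full_frac
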