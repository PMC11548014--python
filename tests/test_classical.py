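"""Classical segmentation stages against brute-force oracles on small toys,
plus end-to-end ROI-count recovery on simulated scenes."""

import numpy as np
import pytest

from dualev.classical import (
    LabeledMask,
    adaptive_threshold,
    clear_border,
    close_and_fill,
    enhance_blobs,
    filter_by_size,
    segment,
    threshold_map,
    watershed_split,
)
from dualev.scene import SceneSpec, generate_scene
from tests.conftest import flood_fill_count


def disk_mask(shape, center, radius):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


class TestEnhanceBlobs:
    def test_flat_input_zero_response(self):
        out = enhance_blobs(np.full((64, 64), 2.0))
        assert np.all(out == 0)

    def test_single_spot_maximum_at_center(self):
        yy, xx = np.mgrid[0:101, 0:101]
        sbr = 1.0 + 3.0 * np.exp(-((yy - 50) ** 2 + (xx - 57) ** 2) / (2 * 2.0**2))
        out = enhance_blobs(sbr)
        r, c = np.unravel_index(np.argmax(out), out.shape)
        assert abs(r - 50) <= 1 and abs(c - 57) <= 1

    def test_two_spots_two_local_maxima(self):
        from skimage.feature import peak_local_max

        yy, xx = np.mgrid[0:101, 0:101]
        sbr = (
            1.0
            + 3.0 * np.exp(-((yy - 30) ** 2 + (xx - 30) ** 2) / (2 * 2.0**2))
            + 3.0 * np.exp(-((yy - 70) ** 2 + (xx - 72) ** 2) / (2 * 2.0**2))
        )
        out = enhance_blobs(sbr)
        peaks = peak_local_max(out.astype(float), min_distance=5, threshold_rel=0.5)
        assert len(peaks) == 2
        found = {tuple(p) for p in peaks}
        assert any(abs(r - 30) <= 1 and abs(c - 30) <= 1 for r, c in found)
        assert any(abs(r - 70) <= 1 and abs(c - 72) <= 1 for r, c in found)


class TestAdaptiveThreshold:
    def brute_force(self, img, block, offset):
        img = np.asarray(img, float)
        h, w = img.shape
        half = block // 2
        out = np.zeros((h, w), bool)
        for r in range(h):
            for c in range(w):
                rs = np.clip(np.arange(r - half, r + half + 1), 0, h - 1)
                cs = np.clip(np.arange(c - half, c + half + 1), 0, w - 1)
                out[r, c] = img[r, c] > img[np.ix_(rs, cs)].mean() + offset
        return out

    def test_constant_image_all_background(self):
        assert not adaptive_threshold(np.full((32, 32), 100)).any()

    def test_matches_brute_force_on_toys(self):
        rng = np.random.default_rng(0)
        step = np.zeros((20, 20))
        step[:, 10:] = 200.0
        noisy = rng.integers(0, 255, size=(20, 20)).astype(float)
        single = np.zeros((20, 20))
        single[7, 11] = 255.0
        for img in (step, noisy, single):
            got = adaptive_threshold(img, block=5, offset=2)
            assert np.array_equal(got, self.brute_force(img, 5, 2))

    def test_single_bright_pixel_detected(self):
        img = np.zeros((20, 20))
        img[7, 11] = 255.0
        assert adaptive_threshold(img, block=5, offset=2)[7, 11]

    def test_even_block_rejected(self):
        with pytest.raises(ValueError):
            adaptive_threshold(np.zeros((8, 8)), block=4)


class TestClearBorder:
    def test_interior_square_untouched(self):
        m = np.zeros((10, 10), bool)
        m[4:7, 4:7] = True
        assert np.array_equal(clear_border(m), m)

    def test_border_component_removed(self):
        m = np.zeros((10, 10), bool)
        m[0:3, 4:6] = True
        assert not clear_border(m).any()

    def test_mixed_components_flood_fill_oracle(self):
        m = np.zeros((16, 16), bool)
        m[0:2, 0:2] = True  # touches border
        m[5:8, 5:8] = True
        m[10:12, 10:13] = True
        out = clear_border(m)
        assert flood_fill_count(out) == 2
        assert flood_fill_count(m) == 3

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        m = rng.random((32, 32)) > 0.6
        once = clear_border(m)
        assert np.array_equal(clear_border(once), once)


class TestCloseAndFill:
    def brute_force(self, mask, closing_area):
        """Fill 4-connected background components of area <= closing_area,
        then fill every enclosed background region."""
        from scipy import ndimage as ndi

        mask = np.asarray(mask, bool).copy()
        lbl, n = ndi.label(~mask, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
        for i in range(1, n + 1):
            if (lbl == i).sum() <= closing_area:
                mask[lbl == i] = True
        return ndi.binary_fill_holes(mask)

    def test_ring_filled(self):
        m = np.zeros((9, 9), bool)
        m[2:7, 2:7] = True
        m[3:6, 3:6] = False  # 3x3 hole
        out = close_and_fill(m)
        assert np.array_equal(out, disk_mask((9, 9), (4, 4), 0) | m | (m ^ out))
        assert out[4, 4]
        assert out.sum() == 25

    def test_solid_square_unchanged_and_idempotent(self):
        m = np.zeros((8, 8), bool)
        m[2:6, 2:6] = True
        out = close_and_fill(m)
        assert np.array_equal(out, m)
        assert np.array_equal(close_and_fill(out), out)

    def test_slit_merging_against_oracle(self):
        # two blocks joined top and bottom with a small enclosed slit
        narrow = np.zeros((12, 12), bool)
        narrow[2:10, 2:5] = True
        narrow[2:10, 6:9] = True
        narrow[2, 5] = narrow[9, 5] = True  # close the slit ends -> enclosed
        out = close_and_fill(narrow, closing_area=16)
        assert np.array_equal(out, self.brute_force(narrow, 16))
        assert out[5, 5]  # slit merged
        # a wide-open slit bigger than closing_area stays
        wide = np.zeros((30, 30), bool)
        wide[2:28, 2:14] = True
        wide[2:28, 16:28] = True
        out2 = close_and_fill(wide, closing_area=16)
        assert np.array_equal(out2, self.brute_force(wide, 16))
        assert not out2[15, 15]


class TestWatershed:
    def test_single_convex_blob_one_label(self):
        m = disk_mask((30, 30), (15, 15), 6)
        lm = watershed_split(m)
        assert lm.n_labels == 1

    def test_empty_mask_zero_labels(self):
        lm = watershed_split(np.zeros((16, 16), bool))
        assert lm.n_labels == 0

    def test_two_overlapping_disks_split(self):
        m = disk_mask((40, 40), (20, 16), 5) | disk_mask((40, 40), (20, 24), 5)
        yy, xx = np.mgrid[0:40, 0:40]
        intensity = np.exp(-((yy - 20) ** 2 + (xx - 16) ** 2) / 18.0) + np.exp(
            -((yy - 20) ** 2 + (xx - 24) ** 2) / 18.0
        )
        enhanced = np.rint(255 * intensity / intensity.max()).astype(np.uint8)
        lm = watershed_split(m, enhanced)
        assert lm.n_labels == 2
        assert np.array_equal(lm.values > 0, m)  # partition covers the mask

    def test_label_count_at_least_component_count(self):
        rng = np.random.default_rng(3)
        m = rng.random((64, 64)) > 0.85
        lm = watershed_split(m)
        assert lm.n_labels >= flood_fill_count(m)


class TestFilterBySize:
    def test_small_and_large_removed(self):
        labels = np.zeros((40, 40), np.int32)
        labels[2:4, 2:3] = 1  # 2 px
        labels[10:15, 10:14] = 2  # 20 px
        lm = filter_by_size(LabeledMask(values=labels), min_area=4, max_area=400)
        assert lm.n_labels == 1
        assert (lm.values == 1).sum() == 20

    def test_aggregate_removed(self):
        labels = np.zeros((60, 60), np.int32)
        labels[5:45, 5:30] = 1  # 1000 px
        lm = filter_by_size(LabeledMask(values=labels), min_area=4, max_area=400)
        assert lm.n_labels == 0

    def test_labels_reindexed_contiguously(self):
        labels = np.zeros((30, 30), np.int32)
        labels[1:2, 1:3] = 1  # too small
        labels[5:10, 5:10] = 2
        labels[15:20, 15:20] = 3
        lm = filter_by_size(LabeledMask(values=labels), min_area=4, max_area=400)
        assert sorted(np.unique(lm.values).tolist()) == [0, 1, 2]

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            filter_by_size(LabeledMask(values=np.zeros((4, 4), np.int32)), 10, 10)

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        from skimage import measure

        labels = measure.label(rng.random((64, 64)) > 0.8)
        lm = filter_by_size(LabeledMask(values=labels.astype(np.int32)))
        lm2 = filter_by_size(lm)
        assert np.array_equal(lm.values, lm2.values)


class TestSegmentPipeline:
    def test_blank_image_zero_rois(self):
        pair, _ = generate_scene(
            SceneSpec(width=512, height=512, n_vesicles=0, seed=0, aggregate_rate=0.0)
        )
        res = segment(pair.mask_image)
        assert res.labeled.n_labels == 0
        assert not res.mask.any()

    def test_deterministic(self, small_scene):
        _, pair, _ = small_scene
        r1 = segment(pair.mask_image)
        r2 = segment(pair.mask_image)
        assert np.array_equal(r1.labeled.values, r2.labeled.values)

    def test_roi_count_within_5_percent_across_seeds(self):
        ratios = []
        for seed in range(10):
            spec = SceneSpec(width=512, height=512, n_vesicles=150, aggregate_rate=0.0, seed=seed)
            pair, _ = generate_scene(spec)
            res = segment(pair.mask_image)
            ratios.append(res.labeled.n_labels / 150)
        assert all(0.95 <= r <= 1.05 for r in ratios), ratios

    def test_aggregates_are_filtered_out(self):
        spec = SceneSpec(width=512, height=512, n_vesicles=50, aggregate_rate=3.0, seed=9)
        pair, gt = generate_scene(spec)
        res = segment(pair.mask_image)
        assert abs(res.labeled.n_labels - 50) <= 3

    def test_mask_matches_truth_reasonably(self, clean_scene):
        from dualev.evaluation import confusion_counts, mean_iou

        _, pair, gt = clean_scene
        res = segment(pair.mask_image)
        iou = mean_iou(confusion_counts(res.mask, gt.truth_mask_map))
        assert iou >= 70.0

    def test_roi_records_populated(self, small_scene):
        _, pair, _ = small_scene
        res = segment(pair.mask_image)
        recs = res.labeled.roi_records
        assert len(recs) == res.labeled.n_labels
        for r in recs[:10]:
            assert r.area >= 4
            assert r.mean_sbr_per_area > 1.0
            r0, c0, r1, c1 = r.bbox
            assert r0 <= r.centroid[0] <= r1 and c0 <= r.centroid[1] <= c1


class TestThresholdMap:
    def test_threshold_and_min_area(self):
        img = np.zeros((32, 32), np.uint8)
        img[5:8, 5:8] = 50  # 9 px blob
        img[20, 20] = 200  # single pixel, below min area
        out = threshold_map(img)
        assert out[6, 6] and not out[20, 20]

    def test_holes_filled(self):
        img = np.zeros((16, 16), np.uint8)
        img[4:11, 4:11] = 30
        img[7, 7] = 0
        assert threshold_map(img)[7, 7]
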