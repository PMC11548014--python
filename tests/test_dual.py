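"""ROI coincidence, population split, and F_p computation."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from dualev.classical import LabeledMask
from dualev.dual import (
    compute_fp,
    match_rois,
    population_histogram,
    roi_intensities,
)


def lm(arr):
    return LabeledMask(values=np.asarray(arr, dtype=np.int32))


class TestMatchRois:
    def test_identical_maps_all_matched(self):
        labels = np.zeros((10, 10), np.int32)
        labels[1:3, 1:3] = 1
        labels[6:8, 6:8] = 2
        res = match_rois(lm(labels), lm(labels))
        assert res.n_mask_rois == res.n_matched == 2

    def test_disjoint_maps_zero_matched(self):
        a = np.zeros((10, 10), np.int32)
        b = np.zeros((10, 10), np.int32)
        a[1:3, 1:3] = 1
        b[6:8, 6:8] = 1
        res = match_rois(lm(a), lm(b))
        assert res.n_matched == 0 and res.pairs == []

    def test_partial_overlap_toy_with_pixel_set_oracle(self):
        mask = np.zeros((20, 20), np.int32)
        mask[2:5, 2:5] = 1
        mask[10:13, 2:5] = 2
        mask[15:18, 14:17] = 3
        target = np.zeros((20, 20), np.int32)
        target[4:7, 4:7] = 1  # overlaps mask 1 at (4,4)
        target[10:11, 4:6] = 2  # overlaps mask 2 row 10
        target[0:2, 18:20] = 3  # overlaps nothing
        res = match_rois(lm(mask), lm(target))
        # pixel-set intersection oracle
        matched_oracle = set()
        for ml in (1, 2, 3):
            pix = set(zip(*np.nonzero(mask == ml)))
            for tl in (1, 2, 3):
                if pix & set(zip(*np.nonzero(target == tl))):
                    matched_oracle.add(ml)
        assert res.n_matched == len(matched_oracle) == 2
        assert set(res.pairs) == {(1, 1), (2, 2)}

    def test_matched_monotone_under_target_dilation(self):
        rng = np.random.default_rng(0)
        from skimage import measure

        mask = measure.label(rng.random((64, 64)) > 0.9).astype(np.int32)
        target_bin = rng.random((64, 64)) > 0.95
        before = match_rois(lm(mask), lm(measure.label(target_bin).astype(np.int32)))
        dilated = ndi.binary_dilation(target_bin, iterations=2)
        after = match_rois(lm(mask), lm(measure.label(dilated).astype(np.int32)))
        assert after.n_matched >= before.n_matched

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            match_rois(lm(np.zeros((4, 4))), lm(np.zeros((5, 5))))

    def test_centroid_rule(self):
        a = np.zeros((20, 20), np.int32)
        b = np.zeros((20, 20), np.int32)
        a[5:8, 5:8] = 1
        b[7:10, 7:10] = 1  # centroid distance ~2.8 < 3
        res = match_rois(lm(a), lm(b), rule="centroid")
        assert res.n_matched == 1


class TestRoiIntensities:
    def test_uniform_sbr_reports_uniform_value(self):
        labels = np.zeros((8, 8), np.int32)
        labels[1:3, 1:3] = 1
        labels[5:7, 5:7] = 2
        vals = roi_intensities(np.full((8, 8), 2.0), lm(labels))
        assert np.allclose(vals, 2.0)

    def test_arithmetic_mean_of_single_roi(self):
        labels = np.zeros((4, 4), np.int32)
        labels[0, 0:4] = 1
        sbr = np.zeros((4, 4))
        sbr[0] = [1.0, 2.0, 3.0, 6.0]
        assert roi_intensities(sbr, lm(labels))[0] == pytest.approx(3.0)

    def test_bound_rois_report_higher_intensity(self, small_scene):
        """AUC > 0.9 separating bound from unbound vesicles by this statistic."""
        from dualev.background import estimate_background, to_sbr
        from dualev.classical import segment

        _, pair, gt = small_scene
        res_mask = segment(pair.mask_image)
        sbr_t = to_sbr(pair.target_image, estimate_background(pair.target_image))
        vals = roi_intensities(sbr_t, res_mask.labeled)
        # assign each ROI to the nearest vesicle via its centroid
        centers = np.array([(v.y, v.x) for v in gt.vesicles])
        bound = np.array([v.bound for v in gt.vesicles])
        labels_bound = []
        for rec in res_mask.labeled.roi_records:
            d = np.linalg.norm(centers - np.array(rec.centroid), axis=1)
            i = int(np.argmin(d))
            if d[i] < 5:
                labels_bound.append(bound[i])
            else:
                labels_bound.append(None)
        keep = [i for i, b in enumerate(labels_bound) if b is not None]
        v = vals[keep]
        b = np.array([labels_bound[i] for i in keep], dtype=bool)
        pos, neg = v[b], v[~b]
        auc = float(np.mean(pos[:, None] > neg[None, :]))
        assert auc > 0.9


class TestPopulationHistogram:
    def test_bimodal_split(self):
        values = [1.0] * 100 + [5.0] * 100
        h = population_histogram(values)
        assert 1.0 < h.split_threshold < 5.0
        assert h.fraction_above == pytest.approx(0.5)
        assert h.counts.sum() == 200

    def test_degenerate_identical_values(self):
        h = population_histogram([2.0] * 50)
        assert h.fraction_above == 0.0

    def test_two_gaussian_mixture_recovery(self):
        rng = np.random.default_rng(0)
        values = np.concatenate(
            [rng.normal(1.0, 0.1, 700), rng.normal(3.0, 0.3, 300)]
        )
        h = population_histogram(values)
        assert h.fraction_above == pytest.approx(0.30, abs=0.03)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            population_histogram([1.0])


class TestComputeFp:
    def test_identical_sets_give_zero(self):
        res = compute_fp([0.2, 0.3, 0.25], [0.2, 0.3, 0.25])
        assert res.fp_mean == pytest.approx(0.0)

    def test_forced_arithmetic(self):
        res = compute_fp([0.35] * 8, [0.05] * 8)
        assert res.fp_mean == pytest.approx(0.30)
        assert res.set_size == 8
        assert all(v == pytest.approx(0.30) for v in res.fp_per_image)

    def test_signed_values_preserved(self):
        res = compute_fp([0.01], [0.10])
        assert res.fp_mean == pytest.approx(-0.09)

    def test_permutation_invariant(self):
        rng = np.random.default_rng(1)
        fa = rng.random(8).tolist()
        fi = rng.random(8).tolist()
        a = compute_fp(fa, fi).fp_mean
        b = compute_fp(fa[::-1], list(np.roll(fi, 3))).fp_mean
        assert a == pytest.approx(b)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            compute_fp([], [0.1])
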