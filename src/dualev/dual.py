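"""Dual-channel ROI matching and the marker-positive fraction F_p.

A vesicle counts as marker-positive when its mask-channel ROI spatially
coincides with a target-channel ROI (default rule: at least one shared
pixel; an alternative centroid-distance rule is available).  Per image, the
bound fraction is (matched mask ROIs) / (all mask ROIs).  F_p subtracts the
mean bound fraction of the IgG isotype control set from each antibody image,
and the per-image values are averaged over the image set (8 pairs in the
standard protocol).

The per-ROI dark-field intensity statistic (integrated SBR over the mask ROI
divided by its area) is pooled into a population-density histogram whose
two-population split (gold-bound vs gold-free vesicles, threshold by
between-class variance maximization) is reported as a cross-check on the
coincidence-based fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from dualev.classical import LabeledMask, SegmentationParams, segment

__all__ = [
    "CoincidenceResult",
    "PopulationHistogram",
    "FpResult",
    "match_rois",
    "roi_intensities",
    "population_histogram",
    "compute_fp",
    "analyze_image_set",
]


@dataclass
class CoincidenceResult:
    n_mask_rois: int
    n_matched: int
    pairs: list[tuple[int, int]]

    @property
    def fraction(self) -> float:
        return self.n_matched / self.n_mask_rois if self.n_mask_rois else 0.0


@dataclass
class PopulationHistogram:
    values: np.ndarray
    bin_edges: np.ndarray
    counts: np.ndarray
    split_threshold: float
    fraction_above: float


@dataclass
class FpResult:
    f_antibody: list[float]
    f_igg: list[float]
    fp_per_image: list[float]
    fp_mean: float
    set_size: int


def match_rois(
    mask_lm: LabeledMask,
    target_lm: LabeledMask,
    rule: str = "overlap",
    centroid_max_dist: float = 3.0,
) -> CoincidenceResult:
    """Match mask ROIs to target ROIs.

    ``rule='overlap'``: a mask ROI matches when it shares >= 1 pixel with any
    target ROI.  ``rule='centroid'``: centroids within ``centroid_max_dist``
    pixels.  Each (mask_label, target_label) pair is listed once.
    """
    ml, tl = mask_lm.values, target_lm.values
    if ml.shape != tl.shape:
        raise ValueError(f"shape mismatch: {ml.shape} vs {tl.shape}")
    n_mask = int(ml.max())
    if rule == "overlap":
        both = (ml > 0) & (tl > 0)
        pairs = np.unique(np.stack([ml[both], tl[both]], axis=1), axis=0) if both.any() else np.empty((0, 2), int)
        pair_list = [(int(a), int(b)) for a, b in pairs]
        matched = len({a for a, _ in pair_list})
    elif rule == "centroid":
        idx_m = np.arange(1, n_mask + 1)
        idx_t = np.arange(1, int(tl.max()) + 1)
        if len(idx_m) == 0 or len(idx_t) == 0:
            return CoincidenceResult(n_mask, 0, [])
        cm = np.array(ndi.center_of_mass(np.ones_like(ml), ml, idx_m))
        ct = np.array(ndi.center_of_mass(np.ones_like(tl), tl, idx_t))
        d2 = ((cm[:, None, :] - ct[None, :, :]) ** 2).sum(axis=2)
        hits = d2 <= centroid_max_dist**2
        pair_list = [
            (int(idx_m[i]), int(idx_t[j])) for i, j in zip(*np.nonzero(hits))
        ]
        matched = int(hits.any(axis=1).sum())
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return CoincidenceResult(n_mask_rois=n_mask, n_matched=matched, pairs=pair_list)


def roi_intensities(sbr_target: np.ndarray, mask_lm: LabeledMask) -> np.ndarray:
    """Per mask ROI: integrated dark-field SBR over the ROI divided by its area."""
    sbr = np.asarray(sbr_target, dtype=np.float64)
    ml = mask_lm.values
    if sbr.shape != ml.shape:
        raise ValueError(f"shape mismatch: {sbr.shape} vs {ml.shape}")
    n = int(ml.max())
    if n == 0:
        return np.empty(0)
    return np.asarray(ndi.mean(sbr, ml, np.arange(1, n + 1)))


def _otsu_threshold(values: np.ndarray, bins: int = 256) -> float:
    """Between-class variance maximization on a 1-D sample."""
    hist, edges = np.histogram(values, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    w = hist.astype(np.float64)
    p = w / w.sum()
    omega = np.cumsum(p)
    mu = np.cumsum(p * centers)
    mu_t = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        between = (mu_t * omega - mu) ** 2 / (omega * (1.0 - omega))
    between[~np.isfinite(between)] = -1.0
    return float(centers[int(np.argmax(between))])


def population_histogram(values, bins: int = 50) -> PopulationHistogram:
    """Histogram of per-ROI intensities with a two-population split.

    Degenerate inputs (all values identical) yield fraction_above = 0, with
    the threshold placed at the common value.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.size < 2:
        raise ValueError("need at least 2 values")
    counts, edges = np.histogram(values, bins=bins)
    if np.ptp(values) == 0:
        thr = float(values[0])
        frac = 0.0
    else:
        thr = _otsu_threshold(values)
        frac = float(np.mean(values > thr))
    return PopulationHistogram(
        values=values, bin_edges=edges, counts=counts, split_threshold=thr, fraction_above=frac
    )


def compute_fp(f_antibody_images, f_igg_images) -> FpResult:
    """F_p per antibody image = its bound fraction minus the mean IgG fraction.

    The set F_p is the arithmetic mean over antibody images; signed values
    are preserved (no clamping).
    """
    fa = [float(v) for v in f_antibody_images]
    fi = [float(v) for v in f_igg_images]
    if not fa or not fi:
        raise ValueError("both image lists must be nonempty")
    igg_mean = float(np.mean(fi))
    fp = [v - igg_mean for v in fa]
    return FpResult(
        f_antibody=fa,
        f_igg=fi,
        fp_per_image=fp,
        fp_mean=float(np.mean(fp)),
        set_size=len(fa),
    )


def _bound_fraction_classical(pair, params: SegmentationParams) -> tuple[float, np.ndarray]:
    res_mask = segment(pair.mask_image, params)
    res_target = segment(pair.target_image, params)
    coin = match_rois(res_mask.labeled, res_target.labeled)
    vals = roi_intensities(res_target.sbr, res_mask.labeled)
    return coin.fraction, vals


def analyze_image_set(
    pairs_ab,
    pairs_igg,
    mode: str = "classical",
    params: SegmentationParams | None = None,
    model=None,
    histogram_bins: int = 50,
) -> tuple[FpResult, PopulationHistogram]:
    """Full dual analysis of an antibody image set against an IgG control set.

    ``mode='classical'`` segments both channels with the classical pipeline;
    ``mode='cnn'`` uses a trained segmentation network (``model``) through
    the patch-predict-stitch route.  The histogram pools the per-ROI target
    intensities of the antibody set.
    """
    if not pairs_ab or not pairs_igg:
        raise ValueError("both image sets must be nonempty")
    params = params or SegmentationParams()

    def fraction_of(pair):
        if mode == "classical":
            return _bound_fraction_classical(pair, params)
        if mode == "cnn":
            if model is None:
                raise ValueError("mode='cnn' requires a trained model")
            from dualev.background import preprocess_to_uint8
            from dualev.classical import build_roi_records, watershed_split
            from dualev.segnet import predict_patch_image

            fracs = []
            sbr_m, img8_m = preprocess_to_uint8(
                pair.mask_image, iterations=params.iterations, sigma_bg=params.sigma_bg,
                gain=params.gain, sbr_floor=params.sbr_floor,
            )
            sbr_t, img8_t = preprocess_to_uint8(
                pair.target_image, iterations=params.iterations, sigma_bg=params.sigma_bg,
                gain=params.gain, sbr_floor=params.sbr_floor,
            )
            lm_m = watershed_split(predict_patch_image(model, img8_m))
            lm_t = watershed_split(predict_patch_image(model, img8_t))
            coin = match_rois(lm_m, lm_t)
            return coin.fraction, roi_intensities(sbr_t, lm_m)
        raise ValueError(f"unknown mode {mode!r}")

    f_ab, pooled = [], []
    for pair in pairs_ab:
        f, vals = fraction_of(pair)
        f_ab.append(f)
        pooled.extend(vals.tolist())
    f_igg = [fraction_of(pair)[0] for pair in pairs_igg]
    fp = compute_fp(f_ab, f_igg)
    if len(pooled) >= 2:
        hist = population_histogram(pooled, bins=histogram_bins)
    else:
        hist = PopulationHistogram(
            values=np.asarray(pooled),
            bin_edges=np.array([0.0, 1.0]),
            counts=np.array([len(pooled)]),
            split_threshold=float("nan"),
            fraction_above=0.0,
        )
    return fp, hist
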