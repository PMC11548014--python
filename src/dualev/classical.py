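"""Classical (non-learned) blob segmentation of SBR images.

Stage 2 of the automatic dual-image analysis: the SBR image is blob-enhanced
(Gaussian smooth, then negated Laplacian so spot centres are maxima, rescaled
to 8 bits), adaptively thresholded against the local mean, cleared of
border-touching components, closed and hole-filled, split by a
marker-controlled watershed, and finally filtered by area so that both
sub-resolution debris and oversized aggregates are dropped.  The surviving
labels with their per-ROI statistics form the final segmentation.

All stages are deterministic; 8-connectivity is used for foreground
throughout (4-connectivity for background when filling holes, the
complementary choice).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import measure, segmentation as skseg
from skimage.feature import peak_local_max

from dualev.background import estimate_background, fft_gaussian, to_sbr, to_uint8

__all__ = [
    "ROIRecord",
    "LabeledMask",
    "SegmentationParams",
    "SegmentationResult",
    "enhance_blobs",
    "adaptive_threshold",
    "clear_border",
    "close_and_fill",
    "watershed_split",
    "filter_by_size",
    "build_roi_records",
    "remove_large_components",
    "segment",
    "classical_map8",
    "threshold_map",
]


@dataclass(frozen=True)
class ROIRecord:
    label: int
    area: int
    centroid: tuple[float, float]  # (row, col)
    bbox: tuple[int, int, int, int]  # (r0, c0, r1, c1), half-open
    mean_sbr_per_area: float | None = None  # integrated SBR over ROI / area


@dataclass
class LabeledMask:
    """Connected-component labeling: 0 = background, labels 1..L contiguous."""

    values: np.ndarray  # int32
    roi_records: list[ROIRecord] = field(default_factory=list)

    @property
    def n_labels(self) -> int:
        return int(self.values.max()) if self.values.size else 0


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable parameters of the classical pipeline (pixels / 8-bit counts)."""

    iterations: int = 10
    sigma_bg: float = 25.0
    gain: float = 100.0
    sbr_floor: float = 1.0
    sigma_blob: float = 2.0
    enhance_gain: float = 300.0
    block: int = 51
    offset: float = 2.0
    closing_area: int = 16
    min_area: int = 4
    max_area: int = 400
    watershed_min_distance: int = 3


@dataclass
class SegmentationResult:
    mask: np.ndarray  # final binary segmentation mask (bool)
    labeled: LabeledMask
    sbr: np.ndarray
    image8: np.ndarray
    enhanced: np.ndarray


def enhance_blobs(sbr: np.ndarray, sigma_blob: float = 2.0, gain: float = 300.0) -> np.ndarray:
    """Gaussian smooth + negated Laplacian, scaled to 8 bits.

    Spot centres become maxima ("higher values constitute features").  The
    scaling is a fixed absolute gain on the nonnegative response (parallel
    to the SBR 8-bit rule), not a per-image max-normalization, so blank or
    noise-only inputs map to (near-)zero instead of amplified noise.
    """
    if sigma_blob <= 0:
        raise ValueError("sigma_blob must be positive")
    g = fft_gaussian(np.asarray(sbr, dtype=np.float64), sigma_blob)
    response = -ndi.laplace(g, mode="nearest")
    np.clip(response, 0.0, None, out=response)
    return np.clip(np.rint(response * gain), 0, 255).astype(np.uint8)


def adaptive_threshold(img: np.ndarray, block: int = 51, offset: float = 2.0) -> np.ndarray:
    """Foreground where value > local mean over a block + offset."""
    if block % 2 == 0 or block < 3:
        raise ValueError("block must be an odd integer >= 3")
    imgf = np.asarray(img, dtype=np.float64)
    local_mean = ndi.uniform_filter(imgf, size=block, mode="nearest")
    return imgf > local_mean + offset


def clear_border(mask: np.ndarray) -> np.ndarray:
    """Remove every connected component that touches the image border."""
    return skseg.clear_border(np.asarray(mask, dtype=bool))


def close_and_fill(mask: np.ndarray, closing_area: int = 16) -> np.ndarray:
    """Area closing (fill background gaps <= closing_area px) then fill all holes.

    Background components are 4-connected (complementary to 8-connected
    foreground).  Idempotent on hole-free input.
    """
    mask = np.asarray(mask, dtype=bool)
    bg_labels = measure.label(~mask, connectivity=1)
    if bg_labels.max() > 0:
        areas = np.bincount(bg_labels.ravel())
        small = areas <= closing_area
        small[0] = False
        mask = mask | small[bg_labels]
    return ndi.binary_fill_holes(mask)


def watershed_split(
    mask: np.ndarray,
    enhanced: np.ndarray | None = None,
    min_distance: int = 3,
) -> LabeledMask:
    """Split touching blobs with a marker-controlled watershed.

    Markers are local maxima of the distance transform (minimum separation
    ``min_distance``); every component is guaranteed at least one marker, so
    the label count never drops below the component count.  The flooding
    surface is the negated enhanced image (blobs split at intensity valleys),
    falling back to the negated distance transform when no enhanced image is
    given.
    """
    mask = np.asarray(mask, dtype=bool)
    comps = measure.label(mask, connectivity=2)
    n_comps = comps.max()
    if n_comps == 0:
        return LabeledMask(values=np.zeros(mask.shape, dtype=np.int32))
    dist = ndi.distance_transform_edt(mask)
    coords = peak_local_max(
        dist, min_distance=min_distance, labels=comps, exclude_border=False
    )
    markers = np.zeros(mask.shape, dtype=np.int32)
    for i, (r, c) in enumerate(coords, start=1):
        markers[r, c] = i
    # ensure every component is seeded
    seeded = np.unique(comps[markers > 0])
    missing = np.setdiff1d(np.arange(1, n_comps + 1), seeded)
    next_label = len(coords) + 1
    for lab in missing:
        rows, cols = np.nonzero(comps == lab)
        k = np.argmax(dist[rows, cols])
        markers[rows[k], cols[k]] = next_label
        next_label += 1
    if enhanced is not None:
        surface = -np.asarray(enhanced, dtype=np.float64)
    else:
        surface = -dist
    labels = skseg.watershed(surface, markers=markers, mask=mask)
    return LabeledMask(values=_relabel(labels))


def _relabel(labels: np.ndarray) -> np.ndarray:
    """Re-index labels to a contiguous 1..L range (order-preserving)."""
    labels = np.asarray(labels)
    present = np.unique(labels)
    present = present[present > 0]
    lut = np.zeros(labels.max() + 1 if labels.size else 1, dtype=np.int32)
    lut[present] = np.arange(1, len(present) + 1, dtype=np.int32)
    return lut[labels]


def filter_by_size(lm: LabeledMask, min_area: int = 4, max_area: int = 400) -> LabeledMask:
    """Drop labels with area < min_area or > max_area; re-index contiguously."""
    if min_area >= max_area:
        raise ValueError("min_area must be < max_area")
    labels = lm.values
    if labels.max() == 0:
        return LabeledMask(values=labels.copy())
    areas = np.bincount(labels.ravel())
    keep = (areas >= min_area) & (areas <= max_area)
    keep[0] = False
    filtered = np.where(keep[labels], labels, 0)
    return LabeledMask(values=_relabel(filtered))


def remove_large_components(mask: np.ndarray, max_area: int) -> np.ndarray:
    """Drop whole connected components larger than max_area.

    Applied to the binary mask before watershed splitting so that oversized
    aggregate artifacts are rejected as single objects rather than being cut
    into spot-sized fragments that would slip past the area filter.
    """
    mask = np.asarray(mask, dtype=bool)
    lbl = measure.label(mask, connectivity=2)
    if lbl.max() == 0:
        return mask
    areas = np.bincount(lbl.ravel())
    keep = areas <= max_area
    keep[0] = False
    return keep[lbl]


def build_roi_records(lm: LabeledMask, sbr: np.ndarray | None = None) -> LabeledMask:
    """Attach per-ROI records (area, centroid, bbox, mean SBR per area)."""
    labels = lm.values
    records: list[ROIRecord] = []
    n = int(labels.max())
    if n > 0:
        idx = np.arange(1, n + 1)
        areas = np.bincount(labels.ravel(), minlength=n + 1)[1:]
        centroids = ndi.center_of_mass(np.ones_like(labels), labels, idx)
        slices = ndi.find_objects(labels)
        means = (
            ndi.mean(np.asarray(sbr, dtype=np.float64), labels, idx)
            if sbr is not None
            else [None] * n
        )
        for i in range(n):
            sl = slices[i]
            records.append(
                ROIRecord(
                    label=int(idx[i]),
                    area=int(areas[i]),
                    centroid=(float(centroids[i][0]), float(centroids[i][1])),
                    bbox=(sl[0].start, sl[1].start, sl[0].stop, sl[1].stop),
                    mean_sbr_per_area=None if sbr is None else float(means[i]),
                )
            )
    lm.roi_records = records
    return lm


def segment(raw: np.ndarray, params: SegmentationParams | None = None) -> SegmentationResult:
    """Full classical pipeline from raw counts to a labeled segmentation."""
    p = params or SegmentationParams()
    bg = estimate_background(raw, iterations=p.iterations, sigma_bg=p.sigma_bg)
    sbr = to_sbr(raw, bg)
    image8 = to_uint8(sbr, gain=p.gain, sbr_floor=p.sbr_floor)
    enhanced = enhance_blobs(sbr, sigma_blob=p.sigma_blob, gain=p.enhance_gain)
    binary = adaptive_threshold(enhanced, block=p.block, offset=p.offset)
    binary = clear_border(binary)
    binary = close_and_fill(binary, closing_area=p.closing_area)
    binary = remove_large_components(binary, p.max_area)
    lm = watershed_split(binary, enhanced, min_distance=p.watershed_min_distance)
    lm = filter_by_size(lm, min_area=p.min_area, max_area=p.max_area)
    lm = build_roi_records(lm, sbr)
    return SegmentationResult(
        mask=lm.values > 0, labeled=lm, sbr=sbr, image8=image8, enhanced=enhanced
    )


def classical_map8(
    img8: np.ndarray, params: SegmentationParams | None = None, clear_borders: bool = False
) -> np.ndarray:
    """Classical labeling of an already-preprocessed 8-bit image.

    Reconstructs the pseudo-SBR implied by the fixed 8-bit scaling and runs
    the classical mask stages (blob enhancement, adaptive threshold, closing
    and hole filling, large- and small-object removal).  Border clearing is
    off by default: an 8-bit tile cut from a larger frame has no physical
    image border.  Used to derive segmentation maps for images that exist
    only in 8-bit form, with the same conventions as the full pipeline.
    """
    p = params or SegmentationParams()
    sbr = p.sbr_floor + np.asarray(img8, dtype=np.float64) / p.gain
    enhanced = enhance_blobs(sbr, sigma_blob=p.sigma_blob, gain=p.enhance_gain)
    binary = adaptive_threshold(enhanced, block=p.block, offset=p.offset)
    if clear_borders:
        binary = clear_border(binary)
    binary = close_and_fill(binary, closing_area=p.closing_area)
    binary = remove_large_components(binary, p.max_area)
    lbl = measure.label(binary, connectivity=2)
    if lbl.max():
        areas = np.bincount(lbl.ravel())
        keep = areas >= p.min_area
        keep[0] = False
        binary = keep[lbl]
    return binary


def threshold_map(img8: np.ndarray, threshold: int = 10, min_area: int = 4) -> np.ndarray:
    """Threshold-and-fill labeling of an 8-bit filtered image.

    Foreground where value >= threshold (the same value-10 criterion that
    defines "useful information" in patch filtering), holes filled, objects
    below min_area dropped.  Used to derive segmentation maps for images that
    have no simulator ground truth, e.g. VAE-generated synthetic images.
    """
    m = np.asarray(img8) >= threshold
    m = ndi.binary_fill_holes(m)
    lbl = measure.label(m, connectivity=2)
    if lbl.max():
        areas = np.bincount(lbl.ravel())
        keep = areas >= min_area
        keep[0] = False
        m = keep[lbl]
    return m
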