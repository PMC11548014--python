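"""Pixel-level segmentation evaluation: mean intersection-over-union.

With n_ij the number of pixels of class i predicted as class j and k
classes, mean IOU = (1/k) * sum_i n_ii / (sum_j n_ij + sum_j n_ji - n_ii),
reported in percent.  Full frames are scored by the patch protocol: each
image is tiled into 256x256 patches (48 for a 1920x1460 frame), a mean IOU
is computed per patch, patches are averaged per image, and the per-image
means are averaged into the global figure.  A class absent from both
prediction and truth contributes IOU 1 (vacuous agreement) by default; the
alternative convention of skipping such classes is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from dualev.patchwork import pad_and_patch

__all__ = ["IOUReport", "confusion_counts", "mean_iou", "evaluate_model"]


@dataclass
class IOUReport:
    n: np.ndarray  # pooled k x k confusion counts
    k: int
    per_patch_iou: list[list[float]]  # [image][patch], percent
    per_image_mean_iou: list[float]  # percent
    global_mean_iou: float  # percent


def confusion_counts(pred: np.ndarray, truth: np.ndarray, k: int = 2) -> np.ndarray:
    """k x k pixel cross-tabulation; n[i, j] = pixels of class i predicted j."""
    pred = np.asarray(pred).astype(np.int64)
    truth = np.asarray(truth).astype(np.int64)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    return np.bincount(truth.ravel() * k + pred.ravel(), minlength=k * k).reshape(k, k)


def mean_iou(n: np.ndarray, vacuous_class_iou: bool = True) -> float:
    """Mean IOU in percent from a confusion matrix.

    Classes empty in both prediction and truth score IOU 1 when
    ``vacuous_class_iou`` (default); otherwise they are skipped.
    """
    n = np.asarray(n, dtype=np.float64)
    k = n.shape[0]
    if n.shape != (k, k) or k < 2:
        raise ValueError("confusion matrix must be square with k >= 2")
    ious = []
    for i in range(k):
        denom = n[i, :].sum() + n[:, i].sum() - n[i, i]
        if denom == 0:
            if vacuous_class_iou:
                ious.append(1.0)
            continue
        ious.append(n[i, i] / denom)
    if not ious:
        return 100.0
    return float(np.mean(ious)) * 100.0


def evaluate_model(
    predict_fn,
    test_images: list[np.ndarray],
    truth_maps: list[np.ndarray],
    patch: int = 256,
    vacuous_class_iou: bool = True,
) -> IOUReport:
    """Patch-protocol evaluation of a binary segmenter on full images.

    ``predict_fn`` maps one image to a binary map of the same shape.  The
    per-image mean equals the plain mean of its patch IOUs (no pixel
    weighting); the global figure is the mean of the per-image means.
    """
    if len(test_images) != len(truth_maps):
        raise ValueError("test_images and truth_maps must be aligned")
    pooled = np.zeros((2, 2), dtype=np.int64)
    per_patch: list[list[float]] = []
    per_image: list[float] = []
    for img, truth in zip(test_images, truth_maps):
        pred = np.asarray(predict_fn(img)) > 0
        truth = np.asarray(truth) > 0
        if pred.shape != truth.shape:
            raise ValueError("prediction and truth shapes differ")
        p_tiles = pad_and_patch(pred, patch=patch)
        t_tiles = pad_and_patch(truth, patch=patch)
        ious = []
        for pt, tt in zip(p_tiles, t_tiles):
            cm = confusion_counts(pt.pixels, tt.pixels)
            pooled += cm
            ious.append(mean_iou(cm, vacuous_class_iou=vacuous_class_iou))
        per_patch.append(ious)
        per_image.append(float(np.mean(ious)))
    return IOUReport(
        n=pooled,
        k=2,
        per_patch_iou=per_patch,
        per_image_mean_iou=per_image,
        global_mean_iou=float(np.mean(per_image)),
    )
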