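"""Cropping full-size images into fixed-size patches and stitching them back.

Images are reflect-padded up to the next multiple of the patch size (the pad
split evenly per side, extra on the bottom/right) and tiled without overlap,
so a 1920 x 1460 frame becomes a padded 2048 x 1536 canvas cut into 8 x 6 =
48 patches of 256 x 256.  ``stitch`` is the exact inverse:
``stitch(pad_and_patch(x)) == x`` bit-for-bit, independent of patch order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Patch",
    "pad_and_patch",
    "filter_training_patches",
    "stitch",
    "save_patches",
    "load_patches",
]

PadSpec = tuple[tuple[int, int], tuple[int, int]]  # ((top, bottom), (left, right))


@dataclass
class Patch:
    pixels: np.ndarray
    origin: tuple[int, int]  # (row, col) in the padded parent
    parent_shape: tuple[int, int]
    pad_spec: PadSpec


def _pad_reflect(img: np.ndarray, pad_spec: PadSpec) -> np.ndarray:
    """Reflect padding, applied in slabs so pads larger than dim-1 also work."""
    out = img
    (top, bottom), (left, right) = pad_spec
    while top or bottom or left or right:
        t = min(top, out.shape[0] - 1)
        b = min(bottom, out.shape[0] - 1)
        l = min(left, out.shape[1] - 1)
        r = min(right, out.shape[1] - 1)
        out = np.pad(out, ((t, b), (l, r)), mode="reflect")
        top, bottom, left, right = top - t, bottom - b, left - l, right - r
    return out


def pad_and_patch(img: np.ndarray, patch: int = 256) -> list[Patch]:
    """Tile an image into non-overlapping patch x patch tiles after padding."""
    img = np.asarray(img)
    if img.size == 0:
        raise ValueError("image must be nonempty")
    h, w = img.shape
    ph = -h % patch
    pw = -w % patch
    pad_spec: PadSpec = ((ph // 2, ph - ph // 2), (pw // 2, pw - pw // 2))
    padded = _pad_reflect(img, pad_spec)
    patches = []
    for r in range(0, padded.shape[0], patch):
        for c in range(0, padded.shape[1], patch):
            patches.append(
                Patch(
                    pixels=padded[r : r + patch, c : c + patch].copy(),
                    origin=(r, c),
                    parent_shape=(h, w),
                    pad_spec=pad_spec,
                )
            )
    return patches


def filter_training_patches(
    patches: list[Patch] | list[np.ndarray],
    min_frac: float = 0.05,
    min_val: int = 10,
) -> list:
    """Keep patches whose fraction of pixels >= min_val is >= min_frac.

    Both comparisons are inclusive: a 256 x 256 patch with exactly 3277
    pixels at value >= 10 (3277/65536 ~ 5.0008%) is kept.
    """
    kept = []
    for p in patches:
        px = p.pixels if isinstance(p, Patch) else np.asarray(p)
        if np.count_nonzero(px >= min_val) / px.size >= min_frac:
            kept.append(p)
    return kept


def stitch(patches: list[Patch]) -> np.ndarray:
    """Reassemble the parent image from a complete non-overlapping tiling."""
    if not patches:
        raise ValueError("no patches to stitch")
    shape = patches[0].parent_shape
    pad_spec = patches[0].pad_spec
    k = patches[0].pixels.shape[0]
    for p in patches:
        if p.parent_shape != shape or p.pad_spec != pad_spec:
            raise ValueError("patches come from different parents")
    (top, _), (left, _) = pad_spec
    ph = shape[0] + pad_spec[0][0] + pad_spec[0][1]
    pw = shape[1] + pad_spec[1][0] + pad_spec[1][1]
    canvas = np.zeros((ph, pw), dtype=patches[0].pixels.dtype)
    coverage = np.zeros((ph // k, pw // k), dtype=np.int32)
    for p in patches:
        r, c = p.origin
        if r % k or c % k or r + k > ph or c + k > pw:
            raise ValueError(f"patch origin {p.origin} not on the tiling grid")
        canvas[r : r + k, c : c + k] = p.pixels
        coverage[r // k, c // k] += 1
    if not np.all(coverage == 1):
        raise ValueError("missing or duplicate tiles in patch list")
    return canvas[top : top + shape[0], left : left + shape[1]]


def save_patches(patches: list[Patch], out_dir) -> None:
    """Write patches as PNGs named ``r{row}_c{col}.png`` plus a JSON manifest."""
    import json
    from pathlib import Path

    from dualev.imageio_utils import write_image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for p in patches:
        write_image(out / f"r{p.origin[0]}_c{p.origin[1]}.png", p.pixels)
    first = patches[0]
    (out / "manifest.json").write_text(
        json.dumps(
            {
                "parent_shape": list(first.parent_shape),
                "pad_spec": [list(first.pad_spec[0]), list(first.pad_spec[1])],
                "patch": int(first.pixels.shape[0]),
            }
        )
    )


def load_patches(in_dir) -> list[Patch]:
    """Inverse of :func:`save_patches`."""
    import json
    import re
    from pathlib import Path

    from dualev.imageio_utils import read_image

    src = Path(in_dir)
    meta = json.loads((src / "manifest.json").read_text())
    parent_shape = tuple(meta["parent_shape"])
    pad_spec = (tuple(meta["pad_spec"][0]), tuple(meta["pad_spec"][1]))
    patches = []
    for path in sorted(src.glob("r*_c*.png")):
        m = re.fullmatch(r"r(\d+)_c(\d+)\.png", path.name)
        if m:
            patches.append(
                Patch(read_image(path), (int(m[1]), int(m[2])), parent_shape, pad_spec)
            )
    return patches
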