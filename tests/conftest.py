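import numpy as np
import pytest

from dualev.background import preprocess_to_uint8
from dualev.scene import SceneSpec, generate_scene


@pytest.fixture(scope="session")
def small_scene():
    """One 512x512 scene with ground truth (150 vesicles, default noise)."""
    spec = SceneSpec(width=512, height=512, n_vesicles=150, seed=11)
    pair, gt = generate_scene(spec)
    return spec, pair, gt


@pytest.fixture(scope="session")
def clean_scene():
    """Noise-free, flat-background, aggregate-free 512x512 scene."""
    from dualev.scene import noiseless_scene

    spec = noiseless_scene(SceneSpec(width=512, height=512, n_vesicles=50, seed=7))
    pair, gt = generate_scene(spec)
    return spec, pair, gt


@pytest.fixture(scope="session")
def scene_images8():
    """8-bit preprocessed mask-channel images of three small scenes."""
    out = []
    for seed in (21, 22, 23):
        pair, gt = generate_scene(SceneSpec(width=512, height=512, n_vesicles=80, seed=seed))
        _, img8 = preprocess_to_uint8(pair.mask_image)
        out.append((img8, gt))
    return out


def flood_fill_count(mask: np.ndarray, connectivity: int = 2) -> int:
    """Brute-force connected-component count by iterative flood fill.

    Independent oracle for component counting: no labeling library involved.
    """
    mask = np.asarray(mask, dtype=bool).copy()
    if connectivity == 2:
        steps = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    h, w = mask.shape
    count = 0
    for r0 in range(h):
        for c0 in range(w):
            if not mask[r0, c0]:
                continue
            count += 1
            stack = [(r0, c0)]
            mask[r0, c0] = False
            while stack:
                r, c = stack.pop()
                for dr, dc in steps:
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < h and 0 <= cc < w and mask[rr, cc]:
                        mask[rr, cc] = False
                        stack.append((rr, cc))
    return count
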