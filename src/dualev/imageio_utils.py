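"""Reading and writing of the image formats used throughout.

16-bit grayscale camera frames travel as TIFF (or PNG); 8-bit filtered images
and binary maps travel as PNG.  Everything in memory is a plain 2-D numpy
array.
"""

from __future__ import annotations

import numpy as np


def read_image(path) -> np.ndarray:
    """Read a grayscale image (TIFF via tifffile, anything else via imageio)."""
    path = str(path)
    if path.lower().endswith((".tif", ".tiff")):
        import tifffile

        img = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        img = iio.imread(path)
    img = np.asarray(img)
    if img.ndim == 3:  # collapse an accidental RGB read
        img = img[..., 0]
    return img


def write_image(path, img: np.ndarray) -> None:
    path = str(path)
    img = np.asarray(img)
    if path.lower().endswith((".tif", ".tiff")):
        import tifffile

        tifffile.imwrite(path, img)
    else:
        import imageio.v3 as iio

        iio.imwrite(path, img)


def write_mask_png(path, mask: np.ndarray) -> None:
    """Binary map -> 8-bit PNG with foreground at 255."""
    write_image(path, (np.asarray(mask) > 0).astype(np.uint8) * 255)
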