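"""Iterative background estimation and signal-to-background (SBR) imaging.

The raw micrograph is first smoothed with a zeroth-order Savitzky-Golay
filter (a separable local mean of window 3).  The smooth background is then
estimated iteratively: each iteration applies a Fourier-domain Gaussian
filter to the reciprocal of the current estimate and takes the reciprocal of
the result (harmonic smoothing, which hugs local minima and therefore the
background rather than the spots), after which any pixel that exceeds the
smoothed original is replaced by the smoothed original ("replace with the
lower value" rule).  Ten iterations are the default.  Dividing the raw image
by the estimated background gives the SBR image, which is ~1 in background
regions; an invented but fixed scaling rule maps it to 8 bits:
``uint8 = clip(round(gain * (SBR - floor)), 0, 255)`` with gain 100 and
floor 1, so pure background maps near 0 and a spot peaking at twice the
background maps near 100.

All spatial filters use nearest-edge extension; the Fourier Gaussian is
applied on an edge-padded copy so that its implicit periodicity does not
leak across the image border.
"""

from __future__ import annotations

import numpy as np
from scipy import fft as _fft
from scipy import ndimage as ndi

__all__ = ["smooth_sg0", "estimate_background", "to_sbr", "to_uint8", "fft_gaussian"]

#: additive guard so reciprocals of 16-bit counts are always finite
_GUARD = 1.0


def smooth_sg0(image: np.ndarray, window: int = 3) -> np.ndarray:
    """Zeroth-order Savitzky-Golay smoothing: a separable windowed mean.

    Applied along both axes with nearest-edge extension.  ``window=1`` is the
    identity; constant images are fixed points.
    """
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be an odd integer >= 1")
    return ndi.uniform_filter(np.asarray(image, dtype=np.float64), size=window, mode="nearest")


def fft_gaussian(image: np.ndarray, sigma: float) -> np.ndarray:
    """Fourier-domain Gaussian filter with edge padding (no wrap-around)."""
    # float32 transforms: values span ~6 decades at most here, far inside
    # single precision, and the FFTs dominate the pipeline's runtime
    img = np.asarray(image, dtype=np.float32)
    pad = int(np.ceil(4.0 * sigma))
    h, w = img.shape
    ph = _fft.next_fast_len(h + 2 * pad)
    pw = _fft.next_fast_len(w + 2 * pad)
    padded = np.pad(img, ((pad, ph - h - pad), (pad, pw - w - pad)), mode="edge")
    spec = _fft.rfft2(padded)
    spec = ndi.fourier_gaussian(spec, sigma, n=pw)
    out = _fft.irfft2(spec, s=(ph, pw))
    return out[pad : pad + h, pad : pad + w].astype(np.float64)


def estimate_background(
    raw: np.ndarray, iterations: int = 10, sigma_bg: float = 25.0
) -> np.ndarray:
    """Estimate the smooth multiplicative background of a spot image.

    Returns a strictly positive float image, pointwise <= the smoothed input.
    The maximum of the estimate is non-increasing in the iteration count.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    raw = np.asarray(raw, dtype=np.float64)
    guarded = raw + _GUARD
    if np.any(guarded <= 0):
        raise ValueError("raw image must be nonnegative (counts)")
    s = smooth_sg0(guarded, 3)
    b = s.copy()
    for _ in range(iterations):
        b = 1.0 / fft_gaussian(1.0 / b, sigma_bg)
        np.minimum(b, s, out=b)
    return b


def to_sbr(raw: np.ndarray, bg: np.ndarray) -> np.ndarray:
    """Pointwise ratio of (guarded) raw image to estimated background."""
    raw = np.asarray(raw, dtype=np.float64)
    bg = np.asarray(bg, dtype=np.float64)
    if raw.shape != bg.shape:
        raise ValueError(f"shape mismatch: raw {raw.shape} vs background {bg.shape}")
    if np.any(bg <= 0):
        raise ValueError("background must be strictly positive")
    sbr = (raw + _GUARD) / bg
    if not np.all(np.isfinite(sbr)):
        raise ValueError("SBR image contains non-finite values")
    return sbr


def to_uint8(sbr: np.ndarray, gain: float = 100.0, sbr_floor: float = 1.0) -> np.ndarray:
    """Fixed 8-bit scaling of an SBR image: clip(round(gain*(SBR-floor)), 0, 255)."""
    if gain <= 0:
        raise ValueError("gain must be positive")
    v = np.rint(gain * (np.asarray(sbr, dtype=np.float64) - sbr_floor))
    return np.clip(v, 0, 255).astype(np.uint8)


def preprocess_to_uint8(
    raw: np.ndarray,
    iterations: int = 10,
    sigma_bg: float = 25.0,
    gain: float = 100.0,
    sbr_floor: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Full raw-counts -> (SBR, 8-bit filtered image) preprocessing chain."""
    bg = estimate_background(raw, iterations=iterations, sigma_bg=sigma_bg)
    sbr = to_sbr(raw, bg)
    return sbr, to_uint8(sbr, gain=gain, sbr_floor=sbr_floor)
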