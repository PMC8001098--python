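"""Image loading and pre-filtering.

Images are handled as 2-D float64 arrays of intensities in [0, 255] — the
"terrain" whose relief the effort features characterize.  Intensities stay
real-valued after filtering (no re-quantization) so that slope estimates are
not contaminated by rounding.
"""

from __future__ import annotations

import os

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

__all__ = ["load_image", "to_grayscale", "median_filter", "homogenize", "as_gray_image"]

# ITU-R BT.601 luminance weights, normalized to sum exactly to one so that
# equal channels map to themselves.
_LUMA = np.array([0.2989, 0.5870, 0.1140])
_LUMA = _LUMA / _LUMA.sum()


def as_gray_image(pixels: np.ndarray) -> np.ndarray:
    """Validate and coerce an array into a grayscale image (2-D float64)."""
    img = np.asarray(pixels, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError(f"grayscale image must be 2-D, got shape {img.shape}")
    if img.shape[0] < 1 or img.shape[1] < 1:
        raise ValueError(f"degenerate image shape {img.shape}")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite intensities")
    return img


def to_grayscale(arr: np.ndarray) -> np.ndarray:
    """Convert a decoded raster (H×W, H×W×3 or H×W×4) to 2-D float64."""
    arr = np.asarray(arr, dtype=np.float64)
    if arr.ndim == 3:
        if arr.shape[2] == 4:  # drop alpha
            arr = arr[:, :, :3]
        if arr.shape[2] == 3:
            arr = arr @ _LUMA
        elif arr.shape[2] == 1:
            arr = arr[:, :, 0]
        else:
            raise ValueError(f"unsupported channel count {arr.shape[2]}")
    elif arr.ndim != 2:
        raise ValueError(f"unsupported image dimensionality {arr.ndim}")
    return as_gray_image(arr)


def load_image(path: str | os.PathLike) -> np.ndarray:
    """Load a PNG/TIFF/JPEG image as a grayscale float64 array in [0, 255].

    RGB inputs are collapsed with fixed luminance weights
    (0.2989, 0.5870, 0.1140).
    """
    try:
        raw = iio.imread(path)
    except Exception as exc:
        raise ValueError(f"cannot read image file {path!r}: {exc}") from exc
    return to_grayscale(raw)


def median_filter(img: np.ndarray, kernel: int = 5) -> np.ndarray:
    """Median pre-filter with a ``kernel``×``kernel`` window.

    Slope estimates are sensitive to impulsive high-frequency noise, hence
    the median rather than a linear smoother.  Borders are handled by edge
    replication so the output keeps the input shape.
    """
    img = as_gray_image(img)
    if not isinstance(kernel, (int, np.integer)) or kernel < 1 or kernel % 2 == 0:
        raise ValueError(f"kernel must be a positive odd integer, got {kernel!r}")
    if kernel > min(img.shape):
        raise ValueError(f"kernel {kernel} exceeds image extent {img.shape}")
    return ndimage.median_filter(img, size=kernel, mode="nearest")


def homogenize(img: np.ndarray, background_sigma: float | None = None) -> np.ndarray:
    """Remove very-low-frequency background trends.

    Subtracts a Gaussian-smoothed background estimate (scale
    ``background_sigma`` pixels, default min(height, width)/4) and adds back
    the global mean, so constant images are fixed points and local relief is
    preserved while large-scale illumination gradients are suppressed.
    """
    img = as_gray_image(img)
    if background_sigma is None:
        background_sigma = min(img.shape) / 4.0
    if not background_sigma > 0:
        raise ValueError(f"background_sigma must be > 0, got {background_sigma!r}")
    background = ndimage.gaussian_filter(img, sigma=background_sigma, mode="nearest")
    return img - background + img.mean()
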