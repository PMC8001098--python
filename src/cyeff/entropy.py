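"""Patch-entropy baseline features.

Thirteen Shannon-entropy statistics of the gray-level histogram, computed
at seven spatial scales: for each of six finite patch sizes (50, 100, 150,
200, 250, 300 px squares) the image is tiled with non-overlapping patches
and the mean and population variance of the per-patch entropies are
recorded; the whole-image scale contributes its single entropy, for
6 × 2 + 1 = 13 values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import as_gray_image

__all__ = ["PATCH_SIZES", "EntropyFeatureVector", "patch_entropy", "extract_ef"]

PATCH_SIZES = (50, 100, 150, 200, 250, 300)
N_EF = 13


@dataclass(frozen=True)
class EntropyFeatureVector:
    values: np.ndarray  # 13 entries, bits
    scale_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        assert self.values.shape == (N_EF,)


def patch_entropy(patch: np.ndarray) -> float:
    """Shannon entropy (bits) of the 256-bin gray-level histogram of a patch.

    Real-valued intensities are rounded to the nearest integer and clipped
    to [0, 255] before binning; empty bins contribute nothing.
    """
    patch = np.asarray(patch, dtype=np.float64)
    if patch.size == 0:
        raise ValueError("patch must be non-empty")
    levels = np.clip(np.rint(patch), 0, 255).astype(np.intp)
    counts = np.bincount(levels.ravel(), minlength=256)
    p = counts[counts > 0] / patch.size
    return float(-(p * np.log2(p)).sum()) + 0.0  # avoid -0.0 for pure patches


def _tile_entropies(img: np.ndarray, size: int) -> np.ndarray:
    """Entropies of all complete size×size tiles anchored at the top-left."""
    h, w = img.shape
    ny, nx = h // size, w // size
    if ny == 0 or nx == 0:
        # Scale larger than the image: the whole image stands as the single
        # patch of that scale so the feature vector stays complete.
        return np.array([patch_entropy(img)])
    return np.array(
        [
            patch_entropy(img[i * size : (i + 1) * size, j * size : (j + 1) * size])
            for i in range(ny)
            for j in range(nx)
        ]
    )


def extract_ef(img: np.ndarray) -> EntropyFeatureVector:
    """The 13 entropy features of an image (at least 50×50 px)."""
    img = as_gray_image(img)
    if img.shape[0] < PATCH_SIZES[0] or img.shape[1] < PATCH_SIZES[0]:
        raise ValueError(
            f"image {img.shape} is smaller than the smallest patch size {PATCH_SIZES[0]}"
        )
    values: list[float] = []
    labels: list[str] = []
    for size in PATCH_SIZES:
        ents = _tile_entropies(img, size)
        values.append(float(ents.mean()))
        values.append(float(ents.var()))  # population variance; 0 for a single patch
        labels.append(f"{size}x{size}_mean")
        labels.append(f"{size}x{size}_var")
    values.append(patch_entropy(img))
    labels.append("full")
    return EntropyFeatureVector(values=np.array(values), scale_labels=tuple(labels))
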