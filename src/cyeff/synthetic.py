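"""Seeded synthetic textures with controlled relief.

Real contact-endoscopy narrow-band images of the larynx show smooth,
low-relief mucosa in benign lesions and dense, high-contrast sinuous
capillaries in malignant ones.  This module emulates that contrast with
two texture families — smooth band-limited noise and dark wiggly "vessel"
strokes on a bright background — so the whole pipeline can be exercised
and benchmarked without any clinical data.  Nothing here claims clinical
realism; it reproduces the relief statistics that the effort features
respond to.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

__all__ = [
    "TextureSpec",
    "LabeledImageSet",
    "make_texture",
    "make_labeled_dataset",
    "default_smooth_spec",
    "default_rough_spec",
]

_KINDS = ("flat", "ramp", "noise", "vessel")


@dataclass(frozen=True)
class TextureSpec:
    """Recipe for one synthetic texture.

    amplitude is the peak-to-peak intensity relief; roughness the spatial
    smoothing scale of the noise field in pixels (larger = smoother);
    n_vessels / vessel_width / wiggle control the vessel pattern.
    """

    kind: str
    size: tuple[int, int] = (150, 150)
    amplitude: float = 100.0
    roughness: float = 3.0
    n_vessels: int = 10
    vessel_width: float = 3.0
    wiggle: float = 6.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        if self.size[0] < 60 or self.size[1] < 60:
            raise ValueError(f"size must be at least (60, 60), got {self.size}")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")


@dataclass(frozen=True)
class LabeledImageSet:
    """A two-class image collection with per-image group ("patient") ids."""

    images: list[np.ndarray]
    labels: np.ndarray  # 0 smooth/benign-like, 1 rough/malignant-like
    group_ids: list[str]

    def __post_init__(self) -> None:
        if not (len(self.images) == len(self.labels) == len(self.group_ids)):
            raise ValueError("images, labels and group_ids must have equal length")
        by_group: dict[str, int] = {}
        for gid, lab in zip(self.group_ids, self.labels):
            if by_group.setdefault(gid, int(lab)) != int(lab):
                raise ValueError(f"group {gid!r} straddles both classes")
        if len(set(int(v) for v in self.labels)) != 2:
            raise ValueError("both classes must be present")


def _noise_field(shape: tuple[int, int], roughness: float, rng: np.random.Generator) -> np.ndarray:
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=max(roughness, 1e-6), mode="wrap")
    lo, hi = f.min(), f.max()
    if hi - lo < 1e-12:
        return np.zeros(shape)
    return (f - lo) / (hi - lo)  # in [0, 1]


def _vessel_image(spec: TextureSpec, rng: np.random.Generator) -> np.ndarray:
    h, w = spec.size
    img = np.full((h, w), 200.0)
    rows = np.arange(h, dtype=float)[:, None]
    sigma = max(spec.vessel_width / 2.0, 0.5)
    x = np.arange(w, dtype=float)
    for _ in range(spec.n_vessels):
        base = rng.uniform(0, h)
        amp = rng.uniform(0.5, 1.5) * spec.wiggle
        period = rng.uniform(0.3, 1.0) * w
        phase = rng.uniform(0, 2 * np.pi)
        walk = np.cumsum(rng.standard_normal(w))
        walk = ndimage.gaussian_filter1d(walk, sigma=8.0, mode="nearest")
        center = base + amp * np.sin(2 * np.pi * x / period + phase) + 0.5 * walk
        # Gaussian stroke profile across rows gives an anti-aliased dark curve.
        depth = spec.amplitude * np.exp(-((rows - center[None, :]) ** 2) / (2 * sigma**2))
        if rng.random() < 0.5:
            depth = depth.T if h == w else depth  # vary orientation on square images
        img -= depth
    return np.clip(img, 0.0, 255.0)


def make_texture(spec: TextureSpec) -> np.ndarray:
    """Render one texture, deterministic under ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.size
    if spec.kind == "flat":
        return np.full((h, w), float(spec.amplitude))
    if spec.kind == "ramp":
        yy, xx = np.mgrid[0:h, 0:w].astype(float)
        t = (yy + xx) / max(h + w - 2, 1)
        return t * spec.amplitude
    if spec.kind == "noise":
        # Band-limited noise centered at mid-gray with peak-to-peak = amplitude.
        f = _noise_field((h, w), spec.roughness, rng)
        center = min(max(128.0, spec.amplitude / 2.0), 255.0 - spec.amplitude / 2.0)
        return center - spec.amplitude / 2.0 + spec.amplitude * f
    return _vessel_image(spec, rng)


def default_smooth_spec(size: tuple[int, int] = (150, 150)) -> TextureSpec:
    """Benign-like class: gently varying low-relief noise."""
    return TextureSpec(kind="noise", size=size, amplitude=10.0, roughness=6.0)


def default_rough_spec(size: tuple[int, int] = (150, 150)) -> TextureSpec:
    """Malignant-like class: high-relief sinuous dark vessels on bright ground."""
    return TextureSpec(kind="vessel", size=size, amplitude=120.0, n_vessels=12, vessel_width=3.0, wiggle=6.0)


def make_labeled_dataset(
    n_per_class: int,
    smooth_spec: TextureSpec | None = None,
    rough_spec: TextureSpec | None = None,
    n_groups: int = 4,
    seed: int | None = None,
) -> LabeledImageSet:
    """Generate a balanced two-class dataset with group structure.

    ``n_groups`` groups per class; images are assigned to groups so that no
    group straddles classes, mirroring patient-exclusive splits.  Per-image
    seeds are spawned from ``seed`` so the whole set is reproducible.
    """
    if not (n_per_class >= n_groups >= 2):
        raise ValueError("need n_per_class >= n_groups >= 2")
    smooth_spec = smooth_spec or default_smooth_spec()
    rough_spec = rough_spec or default_rough_spec()
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2 * n_per_class)]
    images: list[np.ndarray] = []
    labels: list[int] = []
    group_ids: list[str] = []
    for label, (cls_name, spec) in enumerate([("smooth", smooth_spec), ("rough", rough_spec)]):
        for i in range(n_per_class):
            img_seed = child_seeds[label * n_per_class + i]
            images.append(make_texture(replace(spec, seed=img_seed)))
            labels.append(label)
            group_ids.append(f"{cls_name}_g{i * n_groups // n_per_class}")
    return LabeledImageSet(images=images, labels=np.array(labels), group_ids=group_ids)
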