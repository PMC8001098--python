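"""End-to-end feature extraction: preprocessing, features, tables, provenance.

The canonical flow is: median pre-filter (and optional background
homogenization) → random-trajectory effort features and/or patch-entropy
features → one table row per image.  Tables are plain pandas DataFrames
with ``image_id``, ``group_id``, ``label`` id columns followed by feature
columns named FE, FP, EF01..EF13.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .effort import EffortParams, extract_cyeff
from .entropy import extract_ef
from .preprocess import as_gray_image, homogenize, median_filter
from .sampling import SamplingConfig
from .synthetic import LabeledImageSet

__all__ = [
    "PreprocessConfig",
    "EF_NAMES",
    "CYEFF_NAMES",
    "preprocess_image",
    "extract_feature_table",
    "write_feature_table",
]

CYEFF_NAMES = ("FE", "FP")
EF_NAMES = tuple(f"EF{i:02d}" for i in range(1, 14))


@dataclass(frozen=True)
class PreprocessConfig:
    median_kernel: int = 5
    homogenize: bool = True
    background_sigma: float | None = None  # default: min(h, w)/4 at call time


def preprocess_image(img: np.ndarray, cfg: PreprocessConfig | None = None) -> np.ndarray:
    cfg = cfg or PreprocessConfig()
    img = median_filter(as_gray_image(img), cfg.median_kernel)
    if cfg.homogenize:
        img = homogenize(img, cfg.background_sigma)
    return img


def _spawned_seeds(seed: int | None, n: int) -> list[int | None]:
    if seed is None:
        return [None] * n
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def extract_feature_table(
    images: list[np.ndarray] | LabeledImageSet,
    feature_sets: tuple[str, ...] = ("cyeff",),
    image_ids: list[str] | None = None,
    sampling: SamplingConfig | None = None,
    params: EffortParams | None = None,
    preprocessing: PreprocessConfig | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Extract the requested feature sets for every image.

    ``images`` may be a plain list or a :class:`LabeledImageSet`, in which
    case labels and group ids are carried into the table.  Per-image
    trajectory seeds are spawned deterministically from ``seed``.
    """
    unknown = set(feature_sets) - {"cyeff", "ef"}
    if unknown:
        raise ValueError(f"unknown feature sets {sorted(unknown)}")
    if not feature_sets:
        raise ValueError("at least one feature set required")
    sampling = sampling or SamplingConfig()
    params = params or EffortParams()
    if isinstance(images, LabeledImageSet):
        labels = [int(v) for v in images.labels]
        groups = list(images.group_ids)
        imgs = images.images
    else:
        imgs = list(images)
        labels = [0] * len(imgs)
        groups = [f"g{i}" for i in range(len(imgs))]
    if image_ids is None:
        image_ids = [f"img{i:04d}" for i in range(len(imgs))]
    if len(image_ids) != len(imgs):
        raise ValueError("image_ids length mismatch")
    seeds = _spawned_seeds(seed if seed is not None else sampling.seed, len(imgs))
    rows = []
    for img, img_id, gid, lab, img_seed in zip(imgs, image_ids, groups, labels, seeds):
        pre = preprocess_image(img, preprocessing)
        row: dict = {"image_id": img_id, "group_id": gid, "label": lab}
        if "cyeff" in feature_sets:
            feats = extract_cyeff(pre, dataclasses.replace(sampling, seed=img_seed), params)
            row["FE"], row["FP"] = feats.fe, feats.fp
        if "ef" in feature_sets:
            ef = extract_ef(pre)
            row.update(dict(zip(EF_NAMES, ef.values)))
        rows.append(row)
    return pd.DataFrame(rows)


def write_feature_table(
    table: pd.DataFrame,
    path: str | os.PathLike,
    sampling: SamplingConfig | None = None,
    params: EffortParams | None = None,
    preprocessing: PreprocessConfig | None = None,
    seed: int | None = None,
) -> None:
    """Write a feature CSV plus a YAML provenance sidecar with the full config."""
    table.to_csv(path, index=False)
    sidecar = os.fspath(path) + ".config.yaml"
    cfg = {
        "seed": seed,
        "sampling": dataclasses.asdict(sampling or SamplingConfig()),
        "effort_params": dataclasses.asdict(params or EffortParams()),
        "preprocessing": dataclasses.asdict(preprocessing or PreprocessConfig()),
    }
    with open(sidecar, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
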