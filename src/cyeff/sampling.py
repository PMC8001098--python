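"""Random straight-line trajectory sampling and profile sectioning.

A trajectory is a straight segment between two random pixels; the ordered
intensities under its rasterization form a 1-D "stage profile" that the
effort model treats as a race-course elevation profile.  Profiles are then
cut into non-overlapping sections of a fixed index length L.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import as_gray_image

__all__ = [
    "SamplingConfig",
    "TrajectoryProfile",
    "SectionEndpoints",
    "generate_trajectories",
    "rasterize_segment",
    "sectionize",
]

_MAX_REJECTION_TRIES = 10_000


@dataclass(frozen=True)
class SamplingConfig:
    """Sampling parameters.

    n_trajectories
        Number of random trajectories per image (Nk). Default 500: the
        feature values stabilize there and more trajectories do not change
        them appreciably.
    section_length
        Section length L in profile index steps. Default 2.
    min_trajectory_length
        Minimum Euclidean pixel distance between endpoints, so each profile
        carries enough terrain. Default 50 px.
    seed
        RNG seed; identical seed + image + config reproduces trajectories
        bit-for-bit.
    """

    n_trajectories: int = 500
    section_length: int = 2
    min_trajectory_length: float = 50.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_trajectories < 1:
            raise ValueError("n_trajectories must be >= 1")
        if self.section_length < 1:
            raise ValueError("section_length must be >= 1")
        if not self.min_trajectory_length > self.section_length:
            raise ValueError("min_trajectory_length must exceed section_length")


@dataclass(frozen=True)
class TrajectoryProfile:
    """Intensities under one rasterized straight-line trajectory."""

    values: np.ndarray  # 1-D float64
    start_pixel: tuple[int, int]  # (row, col)
    end_pixel: tuple[int, int]

    @property
    def length(self) -> int:
        return int(self.values.shape[0])


@dataclass(frozen=True)
class SectionEndpoints:
    """One profile section: start A and end B as (index, intensity) points."""

    a: tuple[float, float]
    b: tuple[float, float]


def rasterize_segment(
    img: np.ndarray, start: tuple[int, int], end: tuple[int, int]
) -> np.ndarray:
    """Sample the segment at ceil(length)+1 equally spaced points, nearest pixel each.

    Consecutive duplicates are kept so profile samples are uniformly spaced
    along the segment, which the section-time distance computation assumes.
    """
    r0, c0 = start
    r1, c1 = end
    dist = float(np.hypot(r1 - r0, c1 - c0))
    n = int(np.ceil(dist)) + 1
    t = np.linspace(0.0, 1.0, n)
    rows = np.rint(r0 + t * (r1 - r0)).astype(np.intp)
    cols = np.rint(c0 + t * (c1 - c0)).astype(np.intp)
    return img[rows, cols]


def generate_trajectories(
    img: np.ndarray, cfg: SamplingConfig
) -> list[TrajectoryProfile]:
    """Draw ``cfg.n_trajectories`` random straight-line profiles over ``img``.

    Endpoint pairs are drawn independently and uniformly over all pixels;
    pairs closer than ``cfg.min_trajectory_length`` are rejected and redrawn.
    """
    img = as_gray_image(img)
    h, w = img.shape
    diagonal = float(np.hypot(h - 1, w - 1))
    if diagonal < cfg.min_trajectory_length:
        raise ValueError(
            f"image diagonal {diagonal:.1f}px is below the minimum trajectory "
            f"length {cfg.min_trajectory_length}px"
        )
    rng = np.random.default_rng(cfg.seed)
    profiles: list[TrajectoryProfile] = []
    for _ in range(cfg.n_trajectories):
        for _try in range(_MAX_REJECTION_TRIES):
            r0, r1 = rng.integers(0, h, size=2)
            c0, c1 = rng.integers(0, w, size=2)
            if np.hypot(int(r1) - int(r0), int(c1) - int(c0)) >= cfg.min_trajectory_length:
                break
        else:  # pragma: no cover - unreachable for valid inputs
            raise RuntimeError("trajectory endpoint rejection loop exhausted")
        start = (int(r0), int(c0))
        end = (int(r1), int(c1))
        values = rasterize_segment(img, start, end)
        profiles.append(TrajectoryProfile(values=values, start_pixel=start, end_pixel=end))
    return profiles


def sectionize(profile: TrajectoryProfile | np.ndarray, L: int) -> list[SectionEndpoints]:
    """Cut a profile into Ns = floor((Ni-1)/L) consecutive sections of L index steps.

    Section n spans profile indices (n-1)·L .. n·L; interior samples at
    multiples of L are shared as the end of one section and the start of the
    next, so the sections are disjoint in steps but the profile stays
    connected.  Trailing samples that do not fill a section are discarded.
    """
    values = profile.values if isinstance(profile, TrajectoryProfile) else np.asarray(profile)
    if L < 1:
        raise ValueError("section length L must be >= 1")
    ni = values.shape[0]
    if ni < L + 1:
        raise ValueError(f"profile of length {ni} is too short for sections of L={L}")
    ns = (ni - 1) // L
    sections = []
    for n in range(ns):
        i0, i1 = n * L, (n + 1) * L
        sections.append(
            SectionEndpoints(a=(float(i0), float(values[i0])), b=(float(i1), float(values[i1])))
        )
    return sections
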