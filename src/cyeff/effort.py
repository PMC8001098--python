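"""The cyclist-effort texture descriptor.

A grayscale image is read as a hilly terrain: intensity is elevation.  A
virtual cyclist rides straight-line "stage profiles" sampled at random over
the image; on every profile section the resisting forces are

    FG = g · sin(arctan S) · m        (gravity, S = grade fraction)
    FR = g · cos(arctan S) · m · Cr   (rolling resistance)
    FA                                (air resistance, a constant)

and with FT = FG + FR + FA the section power and energy are P = FT·v and
E = P·t, where t is the section traversal time at constant velocity v.
Summing over sections gives a per-trajectory effort; averaging over many
random trajectories gives the two image-level features FE (mean energy, J)
and FP (mean power, W).  Rough, high-relief texture demands more effort
than smooth texture, so (FE, FP) characterize surface roughness.

Pixel units are mapped to meters by assigning the image diagonal the length
of a long road-race course (200 km by default); the same scale is applied
to the intensity axis so that mixed-axis Euclidean distances are coherent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import as_gray_image
from .sampling import SamplingConfig, TrajectoryProfile, generate_trajectories

__all__ = [
    "EffortParams",
    "SectionEffort",
    "TrajectoryEffort",
    "EffortFeatures",
    "gravity_force",
    "rolling_force",
    "section_time",
    "section_slope",
    "section_effort",
    "trajectory_effort",
    "meters_per_unit",
    "extract_cyeff",
]

Point = tuple[float, float]


@dataclass(frozen=True)
class EffortParams:
    """Physical constants of the cyclist model.

    g : gravitational acceleration, m/s² (9.8)
    m : combined cyclist + bike mass, kg (80)
    cr : rolling-resistance coefficient, dimensionless (0.005)
    v : constant cycling velocity, m/s (11, a typical pro-race average)
    fa : constant air-resistance force, N (0 by default; a nonzero value
         only shifts both features by a texture-independent offset)
    course_length : physical length assigned to the longest straight path in
         the image (its diagonal), m (200,000 — a long one-day course)
    slope_mode : "absolute" (default) or "signed".  With signed slopes the
         per-section energies telescope on descents and the energy feature
         degenerates to an endpoint-intensity difference; absolute slopes
         make effort accumulate on climbs and descents alike, which is what
         a roughness descriptor needs.  See the methods note.
    distance_mode : "euclidean" (default) measures section distance between
         the (index, intensity) endpoints with both axes in meters;
         "horizontal" uses the index span only.
    """

    g: float = 9.8
    m: float = 80.0
    cr: float = 0.005
    v: float = 11.0
    fa: float = 0.0
    course_length: float = 200_000.0
    slope_mode: str = "absolute"
    distance_mode: str = "euclidean"

    def __post_init__(self) -> None:
        if not (self.g > 0 and self.m > 0 and self.v > 0 and self.course_length > 0):
            raise ValueError("g, m, v and course_length must be positive")
        if self.cr < 0 or self.fa < 0:
            raise ValueError("cr and fa must be non-negative")
        if self.slope_mode not in ("signed", "absolute"):
            raise ValueError(f"slope_mode must be 'signed' or 'absolute', got {self.slope_mode!r}")
        if self.distance_mode not in ("euclidean", "horizontal"):
            raise ValueError(
                f"distance_mode must be 'euclidean' or 'horizontal', got {self.distance_mode!r}"
            )


@dataclass(frozen=True)
class SectionEffort:
    """Forces, power and energy of one profile section."""

    slope: float  # grade fraction Sn
    time: float  # s
    fg: float  # N
    fr: float  # N
    ft: float  # N, fg + fr + fa
    power: float  # W
    energy: float  # J


@dataclass(frozen=True)
class TrajectoryEffort:
    """Summed effort of one trajectory."""

    power: float  # W
    energy: float  # J
    n_sections: int


@dataclass(frozen=True)
class EffortFeatures:
    """The two image-level features: mean trajectory energy and power."""

    fe: float  # J
    fp: float  # W

    def as_array(self) -> np.ndarray:
        return np.array([self.fe, self.fp])


def _effective_slope(s, params: EffortParams):
    return np.abs(s) if params.slope_mode == "absolute" else s


def gravity_force(s: float, params: EffortParams) -> float:
    """FG = g·sin(arctan S)·m; sign follows S in signed mode."""
    s_eff = _effective_slope(np.asarray(s, dtype=float), params)
    return params.g * params.m * np.sin(np.arctan(s_eff))


def rolling_force(s: float, params: EffortParams) -> float:
    """FR = g·cos(arctan S)·m·Cr; even in S, hence always >= 0."""
    s = np.asarray(s, dtype=float)
    return params.g * params.m * params.cr * np.cos(np.arctan(s))


def section_time(a: Point, b: Point, meters_per_unit: float, params: EffortParams) -> float:
    """Traversal time t = d(A, B)/v with both profile axes scaled to meters."""
    if not meters_per_unit > 0:
        raise ValueError("meters_per_unit must be positive")
    dx = (b[0] - a[0]) * meters_per_unit
    dy = (b[1] - a[1]) * meters_per_unit
    if params.distance_mode == "euclidean":
        d = float(np.hypot(dx, dy))
    else:
        d = abs(dx)
    return d / params.v


def section_slope(a: Point, b: Point, L: int) -> float:
    """Grade fraction S = (B_y - A_y)/L: intensity rise over index run."""
    if L < 1:
        raise ValueError("L must be >= 1")
    return (b[1] - a[1]) / L


def section_effort(
    a: Point, b: Point, L: int, meters_per_unit: float, params: EffortParams
) -> SectionEffort:
    """Full per-section record: slope, time, forces, power, energy."""
    s = section_slope(a, b, L)
    t = section_time(a, b, meters_per_unit, params)
    fg = float(gravity_force(s, params))
    fr = float(rolling_force(s, params))
    ft = fg + fr + params.fa
    power = ft * params.v
    return SectionEffort(slope=s, time=t, fg=fg, fr=fr, ft=ft, power=power, energy=power * t)


def _trajectory_effort_values(
    values: np.ndarray, L: int, mpu: float, params: EffortParams
) -> TrajectoryEffort:
    # Vectorized over sections: endpoints live at profile indices 0, L, 2L, ...
    ni = values.shape[0]
    ns = (ni - 1) // L
    if ns < 1:
        raise ValueError(f"profile of length {ni} is too short for sections of L={L}")
    ys = values[: ns * L + 1 : L]
    dy = np.diff(ys)
    s = dy / L
    fg = params.g * params.m * np.sin(np.arctan(_effective_slope(s, params)))
    fr = params.g * params.m * params.cr * np.cos(np.arctan(s))
    ft = fg + fr + params.fa
    if params.distance_mode == "euclidean":
        d = mpu * np.hypot(float(L), dy)
    else:
        d = np.full(ns, mpu * L)
    t = d / params.v
    p = ft * params.v
    e = p * t
    return TrajectoryEffort(power=float(p.sum()), energy=float(e.sum()), n_sections=ns)


def trajectory_effort(
    profile: TrajectoryProfile | np.ndarray,
    cfg: SamplingConfig,
    params: EffortParams,
    meters_per_unit: float,
) -> TrajectoryEffort:
    """Section a profile and sum the per-section powers and energies."""
    values = profile.values if isinstance(profile, TrajectoryProfile) else np.asarray(profile, float)
    return _trajectory_effort_values(values, cfg.section_length, meters_per_unit, params)


def meters_per_unit(img: np.ndarray, params: EffortParams) -> float:
    """Meters per pixel unit: course_length over the image diagonal.

    The longest straight path in a rectangle is its diagonal; assigning it
    the course length fixes the pixel→meter scale, applied identically to
    the intensity axis.
    """
    img = as_gray_image(img)
    h, w = img.shape
    return params.course_length / float(np.hypot(h, w))


def extract_cyeff(
    img: np.ndarray,
    cfg: SamplingConfig | None = None,
    params: EffortParams | None = None,
) -> EffortFeatures:
    """Compute the two effort features (FE, FP) of a preprocessed image.

    Generates ``cfg.n_trajectories`` random stage profiles, computes each
    trajectory's summed energy Ek and power Pk, and returns their arithmetic
    means.  Fully reproducible given ``cfg.seed``.
    """
    cfg = cfg or SamplingConfig()
    params = params or EffortParams()
    img = as_gray_image(img)
    mpu = meters_per_unit(img, params)
    profiles = generate_trajectories(img, cfg)
    efforts = [
        _trajectory_effort_values(p.values, cfg.section_length, mpu, params) for p in profiles
    ]
    fe = float(np.mean([t.energy for t in efforts]))
    fp = float(np.mean([t.power for t in efforts]))
    return EffortFeatures(fe=fe, fp=fp)
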