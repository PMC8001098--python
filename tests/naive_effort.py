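"""Deliberately naive, loop-based reimplementation of the effort model.

Used as an independent oracle: given the intensity profiles of an image's
trajectories, it recomputes per-section slope, time, forces, power and
energy with plain ``math`` scalar arithmetic, sums per trajectory and
averages.  It shares nothing with the vectorized production path.
"""

import math


def naive_section_effort(ay, by, L, mpu, g, m, cr, v, fa, slope_mode, distance_mode):
    s = (by - ay) / L
    s_eff = abs(s) if slope_mode == "absolute" else s
    fg = g * math.sin(math.atan(s_eff)) * m
    fr = g * math.cos(math.atan(s)) * m * cr
    ft = fg + fr + fa
    if distance_mode == "euclidean":
        d = math.sqrt((L * mpu) ** 2 + ((by - ay) * mpu) ** 2)
    else:
        d = L * mpu
    t = d / v
    power = ft * v
    return power, power * t


def naive_image_features(
    profiles,
    L,
    mpu,
    g=9.8,
    m=80.0,
    cr=0.005,
    v=11.0,
    fa=0.0,
    slope_mode="absolute",
    distance_mode="euclidean",
):
    """(FE, FP) of an image given its trajectory profiles (lists of floats)."""
    energies, powers = [], []
    for values in profiles:
        ni = len(values)
        ns = (ni - 1) // L
        pk = ek = 0.0
        for n in range(1, ns + 1):
            ay = float(values[(n - 1) * L])
            by = float(values[n * L])
            p, e = naive_section_effort(ay, by, L, mpu, g, m, cr, v, fa, slope_mode, distance_mode)
            pk += p
            ek += e
        powers.append(pk)
        energies.append(ek)
    return sum(energies) / len(energies), sum(powers) / len(powers)
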