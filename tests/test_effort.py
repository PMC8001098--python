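import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cyeff import (
    EffortParams,
    SamplingConfig,
    extract_cyeff,
    generate_trajectories,
    gravity_force,
    meters_per_unit,
    rolling_force,
    section_effort,
    section_slope,
    section_time,
    trajectory_effort,
)

SIGNED = EffortParams(slope_mode="signed")
FG_UNIT = 9.8 * 80 * math.sin(math.atan(1.0))  # ~554.372 N at grade 1


class TestForces:
    def test_gravity_zero_on_flat(self, default_params):
        assert gravity_force(0.0, default_params) == 0.0

    def test_gravity_at_unit_grade(self, default_params):
        assert gravity_force(1.0, default_params) == pytest.approx(554.372, abs=1e-3)

    def test_gravity_sign_follows_mode(self):
        assert gravity_force(-1.0, SIGNED) == pytest.approx(-FG_UNIT)
        assert gravity_force(-1.0, EffortParams(slope_mode="absolute")) == pytest.approx(FG_UNIT)

    def test_rolling_on_flat(self, default_params):
        assert rolling_force(0.0, default_params) == pytest.approx(3.92)

    def test_rolling_at_unit_grade(self, default_params):
        assert rolling_force(1.0, default_params) == pytest.approx(2.772, abs=1e-3)

    def test_rolling_vanishes_at_extreme_grade(self, default_params):
        assert rolling_force(1e12, default_params) == pytest.approx(0.0, abs=1e-9)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(s=st.floats(-100, 100, allow_nan=False))
    def test_rolling_never_negative(self, s):
        assert rolling_force(s, EffortParams()) >= 0


class TestSectionGeometry:
    def test_time_horizontal_section(self, default_params):
        assert section_time((0, 0), (2, 0), 1.0, default_params) == pytest.approx(2 / 11)

    def test_time_zero_distance(self, default_params):
        assert section_time((3, 5), (3, 5), 1.0, default_params) == 0.0

    def test_time_includes_intensity_axis(self, default_params):
        assert section_time((0, 0), (2, 2), 1.0, default_params) == pytest.approx(
            math.sqrt(8) / 11
        )

    def test_time_horizontal_distance_mode(self):
        p = EffortParams(distance_mode="horizontal")
        assert section_time((0, 0), (2, 2), 1.0, p) == pytest.approx(2 / 11)

    def test_slope_examples(self):
        assert section_slope((0, 10), (2, 14), 2) == 2.0
        assert section_slope((0, 7), (2, 7), 2) == 0.0
        assert section_slope((0, 14), (2, 10), 2) == -2.0


class TestSectionEffort:
    def test_flat_section_closed_form(self, default_params):
        se = section_effort((0, 0), (2, 0), 2, 1.0, default_params)
        assert se.ft == pytest.approx(3.92)
        assert se.power == pytest.approx(43.12)
        assert se.time == pytest.approx(2 / 11)
        assert se.energy == pytest.approx(7.84)

    def test_unit_grade_section_closed_form(self, default_params):
        se = section_effort((0, 0), (2, 2), 2, 1.0, default_params)
        assert se.ft == pytest.approx(554.372 + 2.772, abs=2e-3)
        assert se.power == pytest.approx(se.ft * 11)
        assert se.energy == pytest.approx(se.ft * math.sqrt(8), rel=1e-9)

    def test_meters_per_unit_scaling_structure(self, default_params):
        a = section_effort((0, 3), (2, 9), 2, 1.0, default_params)
        b = section_effort((0, 3), (2, 9), 2, 2.0, default_params)
        assert b.slope == a.slope
        assert b.ft == pytest.approx(a.ft)
        assert b.power == pytest.approx(a.power)
        assert b.time == pytest.approx(2 * a.time)
        assert b.energy == pytest.approx(2 * a.energy)

    def test_invariant_identities(self, default_params):
        se = section_effort((0, 1), (2, 6), 2, 3.0, default_params)
        assert se.ft == pytest.approx(se.fg + se.fr + default_params.fa)
        assert se.power == pytest.approx(se.ft * default_params.v)
        assert se.energy == pytest.approx(se.power * se.time)


class TestTrajectoryEffort:
    def test_constant_profile_closed_form(self, default_params):
        cfg = SamplingConfig(seed=0)
        eff = trajectory_effort(np.full(51, 9.0), cfg, default_params, 1.0)
        assert eff.n_sections == 25
        assert eff.power == pytest.approx(25 * 43.12)
        assert eff.energy == pytest.approx(25 * 7.84)

    def test_too_short_profile_rejected(self, default_params):
        with pytest.raises(ValueError):
            trajectory_effort(np.array([1.0, 2.0]), SamplingConfig(seed=0), default_params, 1.0)

    def test_shift_invariance(self, default_params, rng):
        cfg = SamplingConfig(seed=0)
        values = rng.integers(0, 256, 80).astype(float)
        a = trajectory_effort(values, cfg, default_params, 5.0)
        b = trajectory_effort(values + 31, cfg, default_params, 5.0)
        assert a == b


class TestMetersPerUnit:
    def test_three_four_five_diagonal(self, default_params):
        assert meters_per_unit(np.zeros((300, 400)), default_params) == pytest.approx(400.0)

    def test_identity_scale(self):
        img = np.zeros((300, 400))
        p = EffortParams(course_length=500.0)
        assert meters_per_unit(img, p) == pytest.approx(1.0)

    def test_square_image(self, default_params):
        assert meters_per_unit(np.zeros((100, 100)), default_params) == pytest.approx(
            200000 / math.sqrt(20000)
        )


class TestExtractCyeff:
    def test_flat_image_matches_per_trajectory_closed_form(self, flat_img, default_params):
        cfg = SamplingConfig(n_trajectories=50, seed=3)
        mpu = meters_per_unit(flat_img, default_params)
        feats = extract_cyeff(flat_img, cfg, default_params)
        ns = np.array(
            [(p.length - 1) // cfg.section_length for p in generate_trajectories(flat_img, cfg)]
        )
        assert feats.fp == pytest.approx(float(np.mean(ns * 43.12)), rel=1e-9)
        assert feats.fe == pytest.approx(float(np.mean(ns * 3.92 * 2 * mpu)), rel=1e-9)

    def test_shift_invariance_exact(self, random_int_img, default_params):
        cfg = SamplingConfig(n_trajectories=20, seed=9)
        a = extract_cyeff(random_int_img, cfg, default_params)
        b = extract_cyeff(random_int_img + 40, cfg, default_params)
        assert a == b

    def test_contrast_monotonicity_absolute_mode(self):
        yy, xx = np.mgrid[0:150, 0:150].astype(float)
        base = (yy + xx) / 4.0
        cfg = SamplingConfig(n_trajectories=60, seed=4)
        params = EffortParams(slope_mode="absolute")
        f1 = extract_cyeff(base, cfg, params)
        f2 = extract_cyeff(2 * base, cfg, params)
        assert f2.fe > f1.fe
        assert f2.fp > f1.fp

    def test_feature_vector_has_two_entries(self, flat_img, default_params):
        feats = extract_cyeff(flat_img, SamplingConfig(n_trajectories=5, seed=0), default_params)
        arr = feats.as_array()
        assert arr.shape == (2,)
        assert arr[0] == feats.fe and arr[1] == feats.fp

    def test_monte_carlo_stability_across_seeds(self):
        # FE scatter across independent trajectory draws shrinks ~1/sqrt(Nk);
        # at the default Nk=500 the coefficient of variation is small (<5%)
        import dataclasses

        from cyeff.synthetic import default_rough_spec, make_texture

        img = make_texture(dataclasses.replace(default_rough_spec(), seed=21))
        params = EffortParams()

        def cv(nk: int) -> float:
            fes = [
                extract_cyeff(img, SamplingConfig(n_trajectories=nk, seed=s), params).fe
                for s in range(8)
            ]
            return float(np.std(fes) / np.mean(fes))

        cv_small, cv_default = cv(50), cv(500)
        assert cv_default < 0.05
        assert cv_small > cv_default

    def test_signed_energy_telescopes_to_endpoint_difference(self, random_int_img):
        # with signed slopes and Euclidean distance, per-trajectory energy is
        # exactly g*m*mpu*(net rise) + g*m*cr*mpu*L*Ns: descents cancel climbs
        params = SIGNED
        cfg = SamplingConfig(n_trajectories=10, seed=6)
        mpu = meters_per_unit(random_int_img, params)
        for p in generate_trajectories(random_int_img, cfg):
            ns = (p.length - 1) // cfg.section_length
            eff = trajectory_effort(p, cfg, params, mpu)
            net = p.values[ns * cfg.section_length] - p.values[0]
            expected = 9.8 * 80 * mpu * net + 9.8 * 80 * 0.005 * mpu * cfg.section_length * ns
            assert eff.energy == pytest.approx(expected, rel=1e-9)


class TestEffortParamsValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"g": 0},
            {"m": -1},
            {"cr": -0.1},
            {"v": 0},
            {"fa": -1},
            {"course_length": 0},
            {"slope_mode": "upward"},
            {"distance_mode": "manhattan"},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            EffortParams(**kwargs)

    def test_defaults(self):
        p = EffortParams()
        assert (p.g, p.m, p.cr, p.v, p.fa, p.course_length) == (
            9.8,
            80.0,
            0.005,
            11.0,
            0.0,
            200_000.0,
        )
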