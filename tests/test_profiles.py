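"""Duct-floor tracing, profile extraction, resampling and averaging."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cochleaquant as cq
from cochleaquant.errors import AnalysisError, ConfigurationError
from cochleaquant.profiles import (DuctFloorPath, IntensityProfile,
                                   average_profiles, extract_profile,
                                   resample_profile, trace_duct_floor)
from cochleaquant.synthetic import RadialSection, analytic_channel_profile
from conftest import noise_free


def mirrored(section):
    flipped = {c: a[:, ::-1].copy() for c, a in section.channels.items()}
    return RadialSection(channels=flipped, pixel_size=section.pixel_size,
                         condition=section.condition, stage=section.stage,
                         metadata={**section.metadata, "medial_on": "right"})


class TestTrace:
    def test_path_within_2um_rms_of_ground_truth(self, e14_noisy_section):
        section, gt = e14_noisy_section
        path = trace_duct_floor(section)
        # compare y at matching x positions
        y_traced = np.interp(gt.path[:, 0], path.points[:, 0], path.points[:, 1])
        rms = np.sqrt(np.mean((y_traced - gt.path[:, 1]) ** 2))
        assert rms < 2.0

    def test_arc_mode_recovers_curved_path(self):
        pre = noise_free("e14_control")
        pre.arc_amplitude = 10.0
        section, gt = cq.make_section(pre, 0)
        path = trace_duct_floor(section)
        assert path.total_length == pytest.approx(gt.arclength[-1], rel=0.01)
        y_traced = np.interp(gt.path[:, 0], path.points[:, 0], path.points[:, 1])
        assert np.sqrt(np.mean((y_traced - gt.path[:, 1]) ** 2)) < 2.0

    def test_blank_image_raises_no_tissue(self):
        blank = RadialSection(channels={"DAPI": np.zeros((50, 50))}, pixel_size=0.5)
        with pytest.raises(AnalysisError, match="no tissue detected"):
            trace_duct_floor(blank)

    def test_tiny_mask_raises_tissue_too_small(self):
        img = np.zeros((50, 50))
        img[25, 25:29] = 1.0
        with pytest.raises(AnalysisError, match="tissue too small"):
            trace_duct_floor(RadialSection(channels={"DAPI": img}, pixel_size=0.5))

    def test_mirrored_section_path_still_medial_first(self, e14_noisy_section):
        section, _ = e14_noisy_section
        p = trace_duct_floor(section)
        pm = trace_duct_floor(mirrored(section))
        # medial end first in both: x starts low for the original, high for
        # the mirrored image, and the profiles must agree
        prof = extract_profile(section, p, "JAG1")
        prof_m = extract_profile(mirrored(section), pm, "JAG1")
        assert prof.total_width == pytest.approx(prof_m.total_width, abs=1.0)
        np.testing.assert_allclose(prof.values, prof_m.values, atol=0.05)


class TestExtract:
    def test_linear_ramp_yields_straight_unit_line(self):
        w, h = 200, 80
        ramp = np.tile(np.linspace(0, 5, w), (h, 1))
        section = RadialSection(channels={"DAPI": np.ones((h, w)), "R": ramp},
                                pixel_size=0.5)
        path = DuctFloorPath(
            points=np.column_stack([np.linspace(0.25, 99.75, w),
                                    np.full(w, 20.0)]),
            arclength=np.linspace(0, 99.5, w))
        prof = extract_profile(section, path, "R", band_halfwidth=0.0)
        np.testing.assert_allclose(prof.values, prof.positions, atol=0.02)
        assert prof.values[0] == 0.0 and prof.values[-1] == 1.0

    def test_constant_image_flags_degenerate_profile(self):
        section = RadialSection(
            channels={"DAPI": np.ones((40, 100)), "C": np.full((40, 100), 3.0)},
            pixel_size=0.5)
        path = DuctFloorPath(
            points=np.column_stack([np.linspace(1, 49, 50), np.full(50, 10.0)]),
            arclength=np.linspace(0, 48, 50))
        prof = extract_profile(section, path, "C")
        assert prof.constant
        assert np.all(prof.values == 0.0)

    def test_unknown_channel_and_out_of_bounds_errors(self, e14_noisy_section):
        section, _ = e14_noisy_section
        path = trace_duct_floor(section)
        with pytest.raises(ConfigurationError, match="unknown channel"):
            extract_profile(section, path, "NOPE")
        far = DuctFloorPath(points=np.array([[0.0, 1e5], [10.0, 1e5]]),
                            arclength=np.array([0.0, 10.0]))
        with pytest.raises(AnalysisError, match="path out of bounds"):
            extract_profile(section, far, "JAG1")

    def test_noise_free_half_max_crossings_match_ground_truth(
            self, e14_noise_free_section):
        section, gt = e14_noise_free_section
        path = trace_duct_floor(section)
        prof = extract_profile(section, path, "JAG1")
        pos_um = prof.positions * prof.total_width
        v = prof.values
        ups = np.where((v[:-1] < 0.5) & (v[1:] >= 0.5))[0]
        downs = np.where((v[:-1] >= 0.5) & (v[1:] < 0.5))[0]
        rise = np.interp(0.5, [v[ups[0]], v[ups[0] + 1]],
                         [pos_um[ups[0]], pos_um[ups[0] + 1]])
        fall_i = downs[-1]
        frac = (v[fall_i] - 0.5) / (v[fall_i] - v[fall_i + 1])
        fall = pos_um[fall_i] + frac * (pos_um[fall_i + 1] - pos_um[fall_i])
        assert rise == pytest.approx(gt.boundary_positions["IS_MS"], abs=1.0)
        assert fall == pytest.approx(gt.boundary_positions["MS_LS"], abs=1.0)

    def test_round_trip_matches_analytic_profile(self, e14_noise_free_section):
        # trace/extract on a noise-free section reproduces the generator's
        # analytic along-path formula to within 2% of range
        section, gt = e14_noise_free_section
        pre = noise_free("e14_control")
        path = trace_duct_floor(section)
        prof = extract_profile(section, path, "SOX2")
        expected = analytic_channel_profile(
            "SOX2", prof.positions * prof.total_width,
            boundaries=gt.boundary_positions,
            sigma=pre.boundary_transition_sigma,
            plateaus=pre.channel_plateaus["SOX2"])
        expected = (expected - expected.min()) / (expected.max() - expected.min())
        rms = np.sqrt(np.mean((prof.values - expected) ** 2))
        assert rms <= 0.02


class TestResample:
    def test_idempotent_on_target_grid(self):
        prof = IntensityProfile("X", np.linspace(0, 1, 101),
                                np.linspace(0, 1, 101) ** 2, 100.0)
        out = resample_profile(prof, 101)
        np.testing.assert_allclose(out.values, prof.values)

    def test_two_point_profile_interpolates_linearly(self):
        prof = IntensityProfile("X", np.array([0.0, 1.0]),
                                np.array([0.0, 1.0]), 100.0)
        out = resample_profile(prof, 101)
        assert out.values[50] == pytest.approx(0.5)
        assert out.values[0] == 0.0 and out.values[-1] == 1.0

    def test_grid_refinement_error_bound(self, e14_noisy_section):
        # piecewise-linear interpolation error of the coarser grid bounds the
        # disagreement between resamplings
        section, _ = e14_noisy_section
        path = trace_duct_floor(section)
        prof = extract_profile(section, path, "SOX2")
        a = resample_profile(resample_profile(prof, 101), 10001)
        b = resample_profile(resample_profile(prof, 1001), 10001)
        h = 1.0 / 100
        second_diff = np.abs(np.diff(prof.values, 2)).max()
        bound = max(second_diff * 2.0, h)  # generous numerical-analysis bound
        assert np.abs(a.values - b.values).max() <= bound

    def test_rejects_degenerate_grid(self):
        prof = IntensityProfile("X", np.array([0.0, 1.0]),
                                np.array([0.0, 1.0]), 100.0)
        with pytest.raises(ConfigurationError):
            resample_profile(prof, 1)


class TestAverage:
    def test_mean_of_identical_profiles_is_identity_with_zero_sd(self):
        prof = IntensityProfile("X", np.linspace(0, 1, 101),
                                np.abs(np.sin(np.linspace(0, 3, 101))), 100.0)
        avg = average_profiles([prof] * 8)
        np.testing.assert_allclose(avg.mean_values,
                                   np.interp(avg.grid, prof.positions, prof.values))
        np.testing.assert_allclose(avg.sd_values, 0.0, atol=1e-12)
        assert avg.n == 8

    def test_symmetric_pair_averages_to_half(self):
        g = np.linspace(0, 1, 101)
        a = IntensityProfile("X", g, g.copy(), 100.0)
        b = IntensityProfile("X", g, 1 - g, 100.0)
        avg = average_profiles([a, b])
        np.testing.assert_allclose(avg.mean_values, 0.5, atol=1e-12)

    def test_rejects_mixed_channels_and_empty_list(self):
        g = np.linspace(0, 1, 11)
        a = IntensityProfile("X", g, g.copy(), 100.0)
        b = IntensityProfile("Y", g, g.copy(), 100.0)
        with pytest.raises(ConfigurationError, match="mixed"):
            average_profiles([a, b])
        with pytest.raises(ConfigurationError):
            average_profiles([])

    def test_permutation_invariance_equals_positionwise_mean_oracle(self):
        rng = np.random.default_rng(0)
        g = np.linspace(0, 1, 101)
        profs = [IntensityProfile("X", g, rng.random(101), 100.0) for _ in range(6)]
        avg1 = average_profiles(profs)
        avg2 = average_profiles(profs[::-1])
        oracle = np.mean([p.values for p in profs], axis=0)
        np.testing.assert_allclose(avg1.mean_values, oracle, atol=1e-12)
        np.testing.assert_allclose(avg1.mean_values, avg2.mean_values)

    def test_averaged_jag1_peak_lies_lateral_of_mybl2_falling_edge(self):
        # the medial marker declines where the medial-sensory marker rises:
        # across a noisy cohort the averaged JAG1 maximum sits lateral to the
        # half-max falling edge of the averaged MYBL2 profile
        pre = cq.get_preset("e14_control")
        jag, myb = [], []
        for _, (sec, _) in zip(range(8), cq.make_cohort(pre, 8, 3)):
            path = trace_duct_floor(sec)
            jag.append(extract_profile(sec, path, "JAG1"))
            myb.append(extract_profile(sec, path, "MYBL2"))
        avg_j = average_profiles(jag)
        avg_m = average_profiles(myb)
        peak_j = avg_j.grid[np.argmax(avg_j.mean_values)]
        v = avg_m.mean_values
        falls = np.where((v[:-1] >= 0.5) & (v[1:] < 0.5))[0]
        fall_m = avg_m.grid[falls[0]]
        assert peak_j > fall_m


class TestNormalizationProperties:
    @given(gain=st.floats(0.1, 50.0), offset=st.floats(-5.0, 5.0),
           seed=st.integers(0, 1000))
    @settings(max_examples=40, deadline=None)
    def test_minmax_invariant_under_affine_rescaling(self, gain, offset, seed):
        rng = np.random.default_rng(seed)
        raw = rng.random(60) * 10
        raw[0], raw[1] = 0.0, 10.0  # guarantee dynamic range
        g = np.linspace(0, 1, 60)
        h, w = 40, 70
        base = np.tile(raw, (h, 1))[:, :w] if w <= 60 else None
        img = np.tile(raw, (h, 1))
        section = RadialSection(channels={"DAPI": np.ones((h, 60)), "M": img},
                                pixel_size=1.0)
        section2 = RadialSection(
            channels={"DAPI": np.ones((h, 60)), "M": gain * img + offset},
            pixel_size=1.0)
        pts = np.column_stack([np.linspace(0.5, 59.5, 60), np.full(60, 20.0)])
        path = DuctFloorPath(points=pts, arclength=np.linspace(0, 59, 60))
        p1 = extract_profile(section, path, "M", band_halfwidth=0.0)
        p2 = extract_profile(section2, path, "M", band_halfwidth=0.0)
        assert p1.values.min() == 0.0 and p1.values.max() == 1.0
        np.testing.assert_allclose(p1.values, p2.values, atol=1e-9)

    def test_pixel_size_invariance_of_profile_shape(self):
        # the same section rendered at two pixel sizes yields the same
        # normalized profile shape within interpolation error
        pre = noise_free("e14_control")
        sec1, _ = cq.make_section(pre, 0)
        pre2 = noise_free("e14_control")
        pre2.pixel_size = 1.0
        sec2, _ = cq.make_section(pre2, 0)
        p1 = extract_profile(sec1, trace_duct_floor(sec1), "JAG1")
        p2 = extract_profile(sec2, trace_duct_floor(sec2), "JAG1")
        r1 = resample_profile(p1, 101)
        r2 = resample_profile(p2, 101)
        np.testing.assert_allclose(r1.values, r2.values, atol=0.03)
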