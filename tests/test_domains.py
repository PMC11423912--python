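"""Boundary calling, width arithmetic and area/intensity measurements."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cochleaquant as cq
from cochleaquant.domains import (DomainBoundaries, compute_widths,
                                  detect_boundaries, marker_width_fraction,
                                  measure_area_intensity, normalize_to_control)
from cochleaquant.errors import (ConfigurationError, InconsistentBoundariesError,
                                 NoBoundaryError)
from cochleaquant.profiles import (IntensityProfile, extract_profile,
                                   trace_duct_floor)
from cochleaquant.synthetic import RadialSection
from conftest import noise_free


def boundary_profiles(section):
    path = trace_duct_floor(section)
    return {ch: extract_profile(section, path, ch)
            for ch in ("JAG1", "ECAD", "SOX2")}


def sigmoid_profile(channel, midpoints, levels, total=200.0, n=101, sigma=3.0):
    """Analytic plateau-sigmoid profile on an n-point grid (normal-CDF edges)."""
    from scipy.special import ndtr
    pos = np.linspace(0, 1, n)
    s = pos * total
    v = np.full(n, levels[0], dtype=float)
    for m, (lo, hi) in zip(midpoints, zip(levels[:-1], levels[1:])):
        v += (hi - lo) * ndtr((s - m) / sigma)
    v = (v - v.min()) / (v.max() - v.min())
    return IntensityProfile(channel, pos, v, total)


class TestDetectBoundaries:
    def test_noise_free_boundaries_within_1um_of_truth(self, e14_noise_free_section):
        section, gt = e14_noise_free_section
        bounds = detect_boundaries(boundary_profiles(section))
        assert bounds.is_ms == pytest.approx(gt.boundary_positions["IS_MS"], abs=1.0)
        assert bounds.ms_ls == pytest.approx(gt.boundary_positions["MS_LS"], abs=1.0)
        assert bounds.ls_os == pytest.approx(gt.boundary_positions["LS_OS"], abs=1.0)
        assert bounds.source_markers == {"IS_MS": "JAG1", "MS_LS": "ECAD",
                                         "LS_OS": "SOX2"}

    def test_constant_jag1_raises_no_boundary(self, e14_noise_free_section):
        section, _ = e14_noise_free_section
        profs = boundary_profiles(section)
        flat = profs["JAG1"]
        profs["JAG1"] = IntensityProfile("JAG1", flat.positions,
                                         np.zeros_like(flat.values),
                                         flat.total_width, constant=True)
        with pytest.raises(NoBoundaryError, match="IS_MS"):
            detect_boundaries(profs)

    def test_missing_channel_raises(self, e14_noise_free_section):
        section, _ = e14_noise_free_section
        profs = boundary_profiles(section)
        del profs["ECAD"]
        with pytest.raises(ConfigurationError, match="ECAD"):
            detect_boundaries(profs)

    def test_affine_intensity_rescaling_leaves_boundaries_unchanged(
            self, e14_noisy_section):
        section, _ = e14_noisy_section
        rescaled = RadialSection(
            channels={c: (7.0 * a + 3.0 if c != "DAPI" else a)
                      for c, a in section.channels.items()},
            pixel_size=section.pixel_size, metadata=dict(section.metadata))
        b1 = detect_boundaries(boundary_profiles(section))
        b2 = detect_boundaries(boundary_profiles(rescaled))
        assert b1.is_ms == pytest.approx(b2.is_ms, abs=1e-6)
        assert b1.ms_ls == pytest.approx(b2.ms_ls, abs=1e-6)
        assert b1.ls_os == pytest.approx(b2.ls_os, abs=1e-6)

    def test_sox2_mode_places_is_ms_at_sox2_rising_edge(self, e14_noise_free_section):
        section, gt = e14_noise_free_section
        bounds = detect_boundaries(boundary_profiles(section),
                                   ms_marker="sox2_minus_ls")
        assert bounds.source_markers["IS_MS"] == "SOX2"
        assert bounds.is_ms == pytest.approx(gt.boundary_positions["IS_MS"], abs=1.0)

    def test_dual_ms_ls_markers_agree_on_synthetic_sections(
            self, e14_noise_free_section):
        # complementary JAG1/E-cadherin: falling JAG1 and rising E-cadherin
        # cross at the same boundary, so the midpoint mode sets no flag
        section, gt = e14_noise_free_section
        bounds = detect_boundaries(boundary_profiles(section), ms_ls_marker="both")
        assert "divergence" not in bounds.flags
        assert bounds.ms_ls == pytest.approx(gt.boundary_positions["MS_LS"], abs=1.0)

    def test_half_max_crossing_matches_sigmoid_midpoint_within_02um(self):
        # analytic oracle: on a 101-point grid over 200 um the recovered
        # half-max crossing equals the sigmoid midpoint to <= 0.2 um
        profs = {
            "JAG1": sigmoid_profile("JAG1", [82.9, 105.7], [0.05, 1.0, 0.05]),
            "ECAD": sigmoid_profile("ECAD", [105.7, 150.2], [0.08, 1.0, 0.10]),
            "SOX2": sigmoid_profile("SOX2", [82.9, 150.2], [0.05, 1.0, 0.05]),
        }
        bounds = detect_boundaries(profs, smoothing_window=1)
        assert bounds.is_ms == pytest.approx(82.9, abs=0.2)
        assert bounds.ms_ls == pytest.approx(105.7, abs=0.2)
        assert bounds.ls_os == pytest.approx(150.2, abs=0.2)

    def test_recovered_is_fraction_monotone_in_generator_truth(self):
        recovered = []
        for is_frac in (0.3, 0.45, 0.55, 0.65, 0.8):
            pre = noise_free("e14_control")
            pre.is_fraction_of_medial = is_frac
            section, _ = cq.make_section(pre, 0)
            w = compute_widths(detect_boundaries(boundary_profiles(section)))
            recovered.append(w.is_frac)
        assert all(a < b for a, b in zip(recovered, recovered[1:]))


class TestComputeWidths:
    @pytest.mark.parametrize("bpos, expect", [
        ((50, 100, 150, 200), dict(is_=50, ms=50, ls=50, os=50,
                                   is_frac=0.5, ls_frac=0.5)),
        ((71, 100, 150, 200), dict(is_=71, ms=29, ls=50, os=50,
                                   is_frac=0.71, ms_frac=0.29)),
    ])
    def test_width_arithmetic(self, bpos, expect):
        b = DomainBoundaries(is_ms=bpos[0], ms_ls=bpos[1], ls_os=bpos[2],
                             lateral_edge=bpos[3])
        w = compute_widths(b)
        for key, val in expect.items():
            assert getattr(w, key) == pytest.approx(val)

    @given(st.lists(st.floats(1.0, 100.0), min_size=4, max_size=4))
    @settings(max_examples=50, deadline=None)
    def test_widths_telescope_and_fractions_sum_to_one(self, gaps):
        cum = np.cumsum(gaps)
        b = DomainBoundaries(is_ms=cum[0], ms_ls=cum[1], ls_os=cum[2],
                             lateral_edge=cum[3])
        w = compute_widths(b)
        assert w.total == pytest.approx(cum[3], abs=1e-9)
        assert w.is_frac + w.ms_frac == pytest.approx(1.0, abs=1e-12)
        assert w.ls_frac + w.os_frac == pytest.approx(1.0, abs=1e-12)

    def test_unordered_boundaries_rejected(self):
        with pytest.raises(InconsistentBoundariesError):
            DomainBoundaries(is_ms=100, ms_ls=50, ls_os=150, lateral_edge=200)


class TestMarkerWidthFraction:
    def test_top_hat_recovers_its_width(self):
        pos = np.linspace(0, 1, 201)
        v = ((pos >= 0.30) & (pos <= 0.75)).astype(float)
        prof = IntensityProfile("KI67", pos, v, 200.0)
        frac = marker_width_fraction(prof, smoothing_window=1)
        assert frac == pytest.approx(0.45, abs=0.01)

    def test_saturated_profile_gives_full_width(self):
        pos = np.linspace(0, 1, 101)
        prof = IntensityProfile("KI67", pos, np.full(101, 1.0), 200.0)
        # constant non-zero normalized profile is flagged constant by
        # extraction; here values are all above threshold by construction
        prof.constant = False
        assert marker_width_fraction(prof, smoothing_window=1) == pytest.approx(1.0)

    def test_constant_zero_profile_raises(self):
        pos = np.linspace(0, 1, 101)
        prof = IntensityProfile("KI67", pos, np.zeros(101), 200.0, constant=True)
        with pytest.raises(NoBoundaryError):
            marker_width_fraction(prof)

    def test_cohort_recovers_preset_band_extent(self):
        # parameter-recovery oracle: measured Ki67 width fraction converges to
        # the drawn generator extents
        pre = cq.get_preset("e15_control")
        measured, truth = [], []
        for sec, gt in cq.make_cohort(pre, 18, 5):
            path = trace_duct_floor(sec)
            prof = extract_profile(sec, path, "KI67")
            measured.append(marker_width_fraction(prof))
            truth.append(gt.drawn["band_extent:KI67"])
        sem = np.std(measured, ddof=1) / np.sqrt(len(measured))
        assert abs(np.mean(measured) - np.mean(truth)) < max(2 * sem, 0.02)


class TestAreaIntensity:
    def test_blank_channel_measures_zero(self):
        section = RadialSection(channels={"B": np.zeros((50, 50))}, pixel_size=0.5)
        m = measure_area_intensity(section, "B", min_threshold=0.5)
        assert m.area == 0.0 and m.total_intensity == 0.0

    def test_constant_channel_arithmetic(self):
        section = RadialSection(channels={"C": np.full((100, 100), 10.0)},
                                pixel_size=0.5)
        m = measure_area_intensity(section, "C", min_threshold=5.0)
        assert m.area == pytest.approx(2500.0)
        assert m.total_intensity == pytest.approx(100_000.0)

    def test_relative_threshold_is_gain_invariant(self, e14_noisy_section):
        section, _ = e14_noisy_section
        m1 = measure_area_intensity(section, "SOX2")
        scaled = RadialSection(
            channels={c: (a * 5.0 if c == "SOX2" else a)
                      for c, a in section.channels.items()},
            pixel_size=section.pixel_size, metadata=dict(section.metadata))
        m2 = measure_area_intensity(scaled, "SOX2")
        assert m2.area == pytest.approx(m1.area, rel=1e-6)
        assert m2.total_intensity == pytest.approx(5.0 * m1.total_intensity, rel=1e-6)

    def test_unknown_channel_raises(self, e14_noisy_section):
        section, _ = e14_noisy_section
        with pytest.raises(ConfigurationError, match="unknown channel"):
            measure_area_intensity(section, "NOPE")


class TestNormalizeToControl:
    def test_identity_gives_zero_percent_change(self):
        vals = [3.0, 4.0, 5.0]
        ch = normalize_to_control(vals, vals)
        assert ch.percent_change == pytest.approx(0.0)
        assert np.mean(ch.normalized) == pytest.approx(1.0)

    def test_doubling_gives_plus_100_percent(self):
        ch = normalize_to_control([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        assert ch.percent_change == pytest.approx(100.0)

    def test_zero_control_mean_rejected(self):
        with pytest.raises(ConfigurationError):
            normalize_to_control([1.0], [0.0, 0.0])

    def test_e15_ki67_cohorts_recover_published_decrease(self):
        # full-pipeline fluorescence change at the published sample sizes
        ctrl = cq.analyze_section_cohort("e15_control", 22, 5)
        cko = cq.analyze_section_cohort("e15_mybl2_cko", 21, 6)
        ch = normalize_to_control(cko["ki67_intensity"], ctrl["ki67_intensity"])
        assert ch.percent_change == pytest.approx(-22.0, abs=2 * 6.0)
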