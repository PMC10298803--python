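"""Line scans, band events, band width, integrals, evoked analysis."""

import numpy as np
import pytest

from tonotopy import widefield
from tonotopy.trace import normalize_dff
from tonotopy.synth import gen_widefield_ic
from tonotopy.types import StimulusLog, SynthConfig
from tonotopy.widefield import (
    BAND_WIDTH_FACTOR,
    activated_area,
    band_width,
    detect_band_events,
    detect_ic_events,
    regional_maxima,
    response_threshold,
    spatial_integral,
    tonotopic_linescan,
    tonotopic_peak_shift,
    unmix_tone_responses,
)

from _oracles import exhaustive_regional_maxima, trapezoid_sum


class TestDetectIcEvents:
    def test_bilateral_event_left_dominant(self):
        left, right = np.zeros(100), np.zeros(100)
        left[50:53] = [0.015, 0.03, 0.015]
        right[50:53] = [0.008, 0.015, 0.008]
        events = detect_ic_events(left, right, frame_rate_hz=10.0)
        assert len(events) == 1
        assert events[0].dominant_side == "left"
        assert events[0].left_amplitude == pytest.approx(0.03)

    def test_subthreshold_event_ignored(self):
        left = np.zeros(100)
        left[50] = 0.005
        assert detect_ic_events(left, np.zeros(100), 10.0) == []

    def test_planted_event_count_recovered(self):
        cfg = SynthConfig(
            seed=5, duration_s=120, frame_rate_hz=10, image_shape=(200, 200),
            noise_sd_dff=0.0, event_rate_per_min=4, event_amplitude_dff=0.5,
        )
        movie, _, gt = gen_widefield_ic(cfg, band_angle_deg=50)
        dff = normalize_dff(movie.data, "pixel_p10").values
        yy, xx = np.mgrid[0:200, 0:200]
        r = gt.extra["radius"]
        lmask = (yy - 100) ** 2 + (xx - 50) ** 2 <= r**2
        rmask = (yy - 100) ** 2 + (xx - 150) ** 2 <= r**2
        events = detect_ic_events(dff[:, lmask].mean(1), dff[:, rmask].mean(1), 10.0)
        assert len(events) == len(gt.extra["band_events"])
        planted_dom = [
            "left" if e["amp_left"] >= e["amp_right"] else "right"
            for e in sorted(gt.extra["band_events"], key=lambda e: e["peak_frame"])
        ]
        assert [e.dominant_side for e in events] == planted_dom


class TestLinescan:
    def test_uniform_image_constant_profile(self):
        movie = np.full((3, 60, 60), 2.0)
        ls = tonotopic_linescan(movie, (30, 30), 30, 9, 45.0)
        assert np.allclose(ls.profile, 2.0)

    def test_angle_zero_gives_column_means(self):
        movie = np.zeros((2, 40, 40))
        movie[:, :, 20] = 1.0  # vertical stripe
        ls = tonotopic_linescan(movie, (20, 20), 21, 5, 0.0)
        profile = ls.profile[:, 0]
        # long axis runs along x at angle 0; stripe at its center position
        assert np.argmax(profile) == 10
        assert profile[10] == pytest.approx(1.0)

    def test_rotated_band_peak_at_planted_position(self):
        # band perpendicular to a 45-degree axis through the image center
        H = W = 120
        yy, xx = np.mgrid[0:H, 0:W]
        theta = np.deg2rad(45.0)
        s = -(yy - 60) * np.sin(theta) + (xx - 60) * np.cos(theta)
        offset = 12.0  # planted band position along the axis
        img = np.exp(-((s - offset) ** 2) / (2 * 4.0**2))
        ls = tonotopic_linescan(img[None], (60, 60), 80, 15, 45.0)
        peak = np.argmax(ls.profile[:, 0])
        expected = (80 - 1) / 2 + offset
        assert abs(peak - expected) <= 1.0

    def test_out_of_bounds_rect_raises(self):
        with pytest.raises(ValueError):
            tonotopic_linescan(np.zeros((1, 30, 30)), (15, 15), 60, 9, 45.0)


class TestBandEvents:
    def test_single_bump_found(self):
        prof = np.zeros((50, 40))
        yy, xx = np.mgrid[0:50, 0:40]
        prof += 0.1 * np.exp(-((yy - 20) ** 2 + (xx - 25) ** 2) / 30.0)
        from tonotopy.widefield import LineScanProfile

        ls = LineScanProfile(prof, (25, 50), 45.0, 10.0)
        events = detect_band_events(ls, threshold=0.02)
        assert events == [(25, 20)]

    def test_flat_profile_no_events(self):
        from tonotopy.widefield import LineScanProfile

        ls = LineScanProfile(np.full((30, 30), 0.5), (25, 30), 45.0, 10.0)
        assert detect_band_events(ls, threshold=0.02) == []

    def test_matches_exhaustive_oracle_on_random_fields(self, rng):
        from scipy.ndimage import gaussian_filter

        for _ in range(10):
            field = gaussian_filter(rng.normal(0, 1, (40, 40)), 2.0)
            got = set(regional_maxima(field, threshold=0.0))
            expected = exhaustive_regional_maxima(field, threshold=0.0)
            assert got == expected

    def test_plateau_counts_once(self):
        img = np.zeros((20, 20))
        img[8:11, 8:11] = 1.0
        assert regional_maxima(img, 0.5) == [(9, 9)]


class TestBandWidth:
    def test_rectangular_band_exact(self):
        prof = np.zeros(100)
        prof[40:52] = 1.0
        assert band_width(prof) == 12

    def test_gaussian_closed_form(self):
        for sigma in (3.0, 5.0, 10.0):
            x = np.arange(200, dtype=float)
            prof = np.exp(-((x - 100) ** 2) / (2 * sigma**2))
            expected = BAND_WIDTH_FACTOR * sigma
            assert abs(band_width(prof) - expected) <= 1.0

    def test_contiguity_about_global_peak_only(self):
        prof = np.zeros(100)
        prof[10:20] = 0.9
        prof[60:70] = 1.0
        assert band_width(prof) == 10  # the secondary band is not counted

    def test_scale_invariance(self, rng):
        prof = np.abs(rng.normal(0, 1, 80)) + 0.1
        assert band_width(prof) == band_width(3.7 * prof)

    def test_zero_profile_raises(self):
        with pytest.raises(ValueError):
            band_width(np.zeros(10))


class TestSpatialIntegral:
    def test_constant_profile(self):
        assert spatial_integral(np.full(100, 2.0)) == pytest.approx(2.0 * 99)

    def test_triangle(self):
        assert spatial_integral(np.array([0.0, 1.0, 0.0])) == pytest.approx(1.0)

    def test_matches_hand_rolled_oracle(self, rng):
        prof = rng.normal(0, 1, 57)
        assert spatial_integral(prof) == pytest.approx(trapezoid_sum(prof), rel=1e-12)

    def test_linearity(self, rng):
        a, b = rng.normal(0, 1, 30), rng.normal(0, 1, 30)
        assert spatial_integral(2 * a + 3 * b) == pytest.approx(
            2 * spatial_integral(a) + 3 * spatial_integral(b)
        )


class TestUnmixing:
    @staticmethod
    def _log(onsets, freqs, levels):
        return StimulusLog(
            stim_id=np.arange(len(onsets)),
            freq_hz=np.asarray(freqs, float),
            level_db=np.asarray(levels, float),
            onset_frame=np.asarray(onsets),
        )

    def test_identical_repeats_average_to_single_response(self):
        fr = 10.0
        trace = np.zeros(400)
        onsets = [50, 150, 250, 350]
        for o in onsets:
            trace[o : o + 10] = 0.2
        log = self._log(onsets, [8000] * 4, [80] * 4)
        tm = unmix_tone_responses(trace, log, fr)
        key = (8000.0, 80.0)
        assert tm.repeats[key] == 4
        assert tm.amplitudes[key] == pytest.approx(0.2)

    def test_noise_reduced_by_sqrt_repeats(self):
        fr = 10.0
        resid = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            trace = r.normal(0, 0.05, 400)
            log = self._log([50, 150, 250, 350], [8000] * 4, [80] * 4)
            tm = unmix_tone_responses(trace, log, fr)
            resid.append(np.std(tm.segments[(8000.0, 80.0)]))
        assert np.mean(resid) == pytest.approx(0.05 / 2.0, rel=0.15)

    def test_overlapping_windows_rejected(self):
        log = self._log([50, 60], [8000, 8000], [80, 80])
        with pytest.raises(ValueError):
            unmix_tone_responses(np.zeros(200), log, 10.0)

    def test_no_response_amplitude_near_zero(self):
        log = self._log([50, 150], [8000] * 2, [80] * 2)
        tm = unmix_tone_responses(np.zeros(300), log, 10.0)
        assert tm.amplitudes[(8000.0, 80.0)] == pytest.approx(0.0)


class TestResponseThreshold:
    def test_exact_crossing_at_tested_level(self):
        # amplitude equals the criterion exactly at 60 dB and exceeds above it
        levels = np.array([40.0, 50, 60, 70])
        amps = np.array([0.0, 0.0, 0.02, 0.10])
        res = response_threshold(levels, amps, baseline_mean=0.0, baseline_sd=0.01)
        assert res.threshold_db == pytest.approx(60.0)

    def test_all_subcriterion_censored(self):
        res = response_threshold(
            np.array([40.0, 60.0]), np.array([0.001, 0.002]),
            baseline_mean=0.01, baseline_sd=0.01,
        )
        assert res.censored

    def test_interpolated_crossing_matches_algebra(self):
        levels = np.array([40.0, 50, 60, 70])
        amps = np.array([0.0, 0.0, 0.01, 0.03])
        res = response_threshold(levels, amps, baseline_mean=0.0, baseline_sd=0.01)
        # criterion 0.02 crossed between 60 and 70: 60 + 10*(0.02-0.01)/0.02
        assert res.threshold_db == pytest.approx(65.0)

    def test_planted_sigmoid_threshold_recovered(self):
        cfg = SynthConfig(
            seed=9, duration_s=70, frame_rate_hz=10, image_shape=(160, 160),
            noise_sd_dff=0.0,
        )
        levels = np.arange(40.0, 101.0, 10.0)
        onsets = np.arange(20, 20 + 100 * len(levels), 100)
        log = StimulusLog(
            stim_id=np.arange(len(levels)),
            freq_hz=np.full(len(levels), 9500.0),
            level_db=levels,
            onset_frame=onsets,
        )
        movie, _, gt = gen_widefield_ic(cfg, tone_schedule=log, evoked_threshold_db=70.0)
        dff = normalize_dff(movie.data, "pixel_p10").values
        yy, xx = np.mgrid[0:160, 0:160]
        rmask = (yy - 80) ** 2 + (xx - 120) ** 2 <= gt.extra["radius"] ** 2
        tm = unmix_tone_responses(dff[:, rmask].mean(1), log, 10.0)
        amps = np.array([tm.amplitudes[(9500.0, float(l))] for l in levels])
        res = response_threshold(levels, amps, baseline_mean=0.0, baseline_sd=0.0)
        assert abs(res.threshold_db - 70.0) <= 10.0


class TestActivatedArea:
    def test_uniform_suprathreshold_area(self):
        img = np.full((100, 100), 0.2)
        assert activated_area(img, pixel_scale_um=10.0) == pytest.approx(1.0)

    def test_subthreshold_zero(self):
        assert activated_area(np.full((50, 50), 0.1), 10.0) == 0.0

    def test_disk_area_within_pixelization(self):
        yy, xx = np.mgrid[0:200, 0:200]
        r = 40
        img = np.where((yy - 100) ** 2 + (xx - 100) ** 2 <= r**2, 0.3, 0.0)
        area = activated_area(img, pixel_scale_um=10.0)
        assert area == pytest.approx(np.pi * (r * 10 / 1000) ** 2, rel=0.05)


class TestPeakShift:
    def test_planted_tonotopy_linear_in_log_frequency(self):
        freqs = 3000.0 * 2.0 ** np.arange(5)
        profiles = {}
        x = np.arange(100, dtype=float)
        for i, f in enumerate(freqs):
            profiles[f] = np.exp(-((x - (20 + 15 * i)) ** 2) / 50.0)
        out = tonotopic_peak_shift(profiles)
        pos = np.array([out["position"][f] for f in freqs])
        r = np.corrcoef(np.log2(freqs), pos)[0, 1]
        assert r**2 > 0.99
        assert out["shift_vs_lowest_freq"][freqs[0]] == 0.0

    def test_identical_bands_zero_shift(self):
        prof = np.exp(-((np.arange(50) - 25.0) ** 2) / 20.0)
        out = tonotopic_peak_shift({1000.0: prof, 2000.0: prof.copy()})
        assert all(v == 0.0 for v in out["shift_vs_lowest_freq"].values())

    def test_reference_switch_is_constant_offset(self, rng):
        freqs = [1000.0, 2000.0, 4000.0]
        profiles = {f: rng.random(60) for f in freqs}
        out = tonotopic_peak_shift(profiles)
        diffs = [
            out["shift_vs_medial"][f] - out["shift_vs_lowest_freq"][f] for f in freqs
        ]
        assert np.ptp(diffs) == pytest.approx(0.0)
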