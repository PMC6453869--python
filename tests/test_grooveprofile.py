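"""Profile extraction, FWHM peak metrics, tracking, and series summaries."""

import numpy as np
import pytest

from condensia import grooveprofile as gp
from condensia import synthgen
from condensia.grooveprofile import (
    CondensationMeasurement,
    GrooveROI,
    aspect_ratio,
    axial_profile,
    detect_condensations,
    plateau_time,
    track_backwards,
)
from conftest import make_groove_spec

FWHM = synthgen.FWHM_PER_SIGMA


def roi_for(spec):
    h, w = spec.frame_shape
    return GrooveROI(
        x0=0, y0=0, x1=w, y1=h,
        nominal_width=spec.groove_width_um,
        pixel_size=spec.pixel_size_um,
    )


def gaussian_profile_frame(shape, center, sigma_x, sigma_y, amp=1.0):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return amp * np.exp(
        -0.5 * (((xx - center[1]) / sigma_x) ** 2 + ((yy - center[0]) / sigma_y) ** 2)
    )


class TestAxialProfile:
    def test_uniform_frame_flat_profile(self):
        roi = GrooveROI(x0=0, y0=0, x1=50, y1=20, pixel_size=1.0)
        prof = axial_profile(np.full((20, 50), 3.5), roi, "major")
        assert prof.intensities == pytest.approx(3.5)
        assert len(prof.positions) == 50
        assert np.diff(prof.positions) == pytest.approx(1.0)

    def test_ridge_argmax_at_true_center(self):
        frame = gaussian_profile_frame((40, 200), (20, 83.0), 12, 8)
        roi = GrooveROI(x0=0, y0=0, x1=200, y1=40, pixel_size=1.0)
        prof = axial_profile(frame, roi, "major")
        assert abs(prof.positions[np.argmax(prof.intensities)] - 83.0) <= 1.0

    def test_averaging_reduces_noise_variance(self):
        rng = np.random.default_rng(0)
        n_rows = 64
        frame = rng.normal(0, 1.0, size=(n_rows, 4000))
        roi = GrooveROI(x0=0, y0=0, x1=4000, y1=n_rows, pixel_size=1.0)
        prof = axial_profile(frame, roi, "major")
        assert prof.intensities.var() == pytest.approx(1.0 / n_rows, rel=0.15)

    def test_roi_outside_image_errors(self):
        roi = GrooveROI(x0=0, y0=0, x1=100, y1=100)
        with pytest.raises(ValueError):
            axial_profile(np.zeros((50, 50)), roi, "major")

    def test_vertical_groove_is_transposed(self):
        frame = np.zeros((60, 20))
        frame[15, :] = 1.0
        roi = GrooveROI(x0=0, y0=0, x1=20, y1=60, long_axis="vertical", pixel_size=1.0)
        prof = axial_profile(frame, roi, "major")
        assert len(prof.positions) == 60
        assert np.argmax(prof.intensities) == 15


class TestDetectCondensations:
    def test_gaussian_fwhm_identity(self):
        sigma = 15.0
        frame = gaussian_profile_frame((40, 300), (20, 150), sigma, 10)
        roi = GrooveROI(x0=0, y0=0, x1=300, y1=40, pixel_size=1.0)
        prof = axial_profile(frame, roi, "major")
        peaks = detect_condensations(prof, min_prominence=0.01)
        assert len(peaks) == 1
        assert peaks[0]["fwhm"] == pytest.approx(FWHM * sigma, abs=2.0)

    def test_triangular_peak_fwhm_is_half_base(self):
        base = 40
        y = np.r_[np.zeros(30), np.linspace(0, 1, base // 2), np.linspace(1, 0, base // 2), np.zeros(30)]
        prof = gp.AxialProfile(
            positions=(np.arange(y.size) + 0.5) * 1.0, intensities=y, axis="major",
            pixel_size=1.0,
        )
        peaks = detect_condensations(prof, min_prominence=0.1)
        assert len(peaks) == 1
        assert peaks[0]["fwhm"] == pytest.approx(base / 2, abs=1.5)

    def test_prominence_threshold_excludes_weak_bump(self):
        sigma = 10.0
        frame = (
            gaussian_profile_frame((30, 400), (15, 100), sigma, 8, amp=1.0)
            + gaussian_profile_frame((30, 400), (15, 160), sigma, 8, amp=0.8)
            + gaussian_profile_frame((30, 400), (15, 300), sigma, 8, amp=0.05)
        )
        roi = GrooveROI(x0=0, y0=0, x1=400, y1=30, pixel_size=1.0)
        prof = axial_profile(frame, roi, "major")
        peaks = detect_condensations(prof, min_prominence=0.1)
        assert len(peaks) == 2

    def test_no_peaks_empty_list(self):
        prof = gp.AxialProfile(
            positions=np.arange(50) + 0.5,
            intensities=np.linspace(0, 1, 50),
            axis="major",
        )
        assert detect_condensations(prof, min_prominence=0.05) == []

    def test_prominence_scales_linearly_with_amplitude(self):
        frame = gaussian_profile_frame((30, 300), (15, 150), 12, 9, amp=0.6)
        roi = GrooveROI(x0=0, y0=0, x1=300, y1=30, pixel_size=1.0)
        p1 = detect_condensations(axial_profile(frame, roi, "major"), 0.01)
        p3 = detect_condensations(axial_profile(3.0 * frame, roi, "major"), 0.01)
        assert p3[0]["prominence"] == pytest.approx(3 * p1[0]["prominence"], rel=1e-6)


class TestMeasureCondensation:
    def test_isotropic_blob_width_equals_length(self):
        spec = make_groove_spec(
            n_timepoints=1,
            noise_sd=0.0,
            condensations=[
                synthgen.CondensationParams(
                    center_um=250, final_length_um=50, final_width_um=50,
                    growth_midpoint_h=-50,
                )
            ],
        )
        stack, _ = synthgen.generate_groove_series(spec)
        ms = gp.measure_frame(stack[0], roi_for(spec), min_prominence=0.05)
        assert len(ms) == 1
        assert ms[0].width == pytest.approx(ms[0].length, rel=0.05)

    def test_anisotropic_blob_recovers_truth(self):
        spec = make_groove_spec(
            n_timepoints=1,
            noise_sd=0.02,
            condensations=[
                synthgen.CondensationParams(
                    center_um=250, final_length_um=80, final_width_um=40,
                    growth_midpoint_h=-50, amplitude_start=1.0, amplitude_end=1.0,
                )
            ],
        )
        stack, truth = synthgen.generate_groove_series(spec)
        ms = gp.measure_frame(stack[0], roi_for(spec))
        assert len(ms) == 1
        assert ms[0].length == pytest.approx(80.0, rel=0.05)
        assert ms[0].width == pytest.approx(40.0, rel=0.05)

    def test_blob_wider_than_groove_is_clipped(self):
        spec = make_groove_spec(
            groove_width_um=40.0,
            n_timepoints=1,
            noise_sd=0.0,
            condensations=[
                synthgen.CondensationParams(
                    center_um=250, final_length_um=60, final_width_um=39.9,
                    growth_midpoint_h=-50,
                )
            ],
        )
        stack, _ = synthgen.generate_groove_series(spec)
        ms = gp.measure_frame(stack[0], roi_for(spec), min_prominence=0.05)
        assert ms[0].width <= 40.0 + 1e-9


class TestDeriveMetrics:
    def make_roi(self, width):
        return GrooveROI(x0=0, y0=0, x1=500, y1=100, nominal_width=width, pixel_size=1.0)

    def test_constrained_aspect_ratio(self):
        assert aspect_ratio(40.0, 20.0, self.make_roi(100.0)) == pytest.approx(2.0)

    def test_constrained_can_drop_below_one(self):
        assert aspect_ratio(30.0, 60.0, self.make_roi(200.0)) == pytest.approx(0.5)

    def test_unconstrained_uses_longest_over_shortest(self):
        roi300 = self.make_roi(300.0)
        assert aspect_ratio(40.0, 50.0, roi300) == pytest.approx(1.25)
        assert aspect_ratio(40.0, 50.0, self.make_roi("TCP")) == pytest.approx(1.25)
        assert aspect_ratio(50.0, 40.0, roi300) >= 1.0

    def test_density_per_100um(self):
        ms = [
            CondensationMeasurement(position=p, length=30, width=20, prominence=1.0)
            for p in np.linspace(20, 480, 18)
        ]
        out = gp.derive_metrics(ms, self.make_roi(100.0))
        assert out["per_100um"] == pytest.approx(3.6)

    def test_zero_width_flagged_missing(self):
        assert np.isnan(aspect_ratio(40.0, np.nan, self.make_roi(100.0)))


class TestTrackBackwards:
    @staticmethod
    def m(pos, t, length=30.0):
        return CondensationMeasurement(
            position=pos, length=length, width=20.0, prominence=1.0, timepoint=t
        )

    def test_stationary_peaks_full_tracks(self):
        frames = [[self.m(100, t), self.m(300, t)] for t in range(5)]
        tracks = track_backwards(frames)
        assert len(tracks) == 2
        for tr in tracks:
            assert len(tr.measurements) == 5
            assert tr.establishment_time == 0
            assert tr.timepoints == sorted(tr.timepoints)

    def test_late_appearance_sets_establishment(self):
        frames = [[self.m(100, t)] for t in range(6)]
        for t in range(3, 6):
            frames[t].append(self.m(300, t))
        tracks = track_backwards(frames)
        est = sorted(tr.establishment_time for tr in tracks)
        assert est == [0, 3]

    def test_contested_candidate_goes_to_closer_track(self):
        # two final peaks, one earlier candidate at 100: closer one links,
        # the other establishes at the final frame
        frames = [
            [self.m(100, 0)],
            [self.m(104, 1), self.m(112, 1)],
        ]
        tracks = track_backwards(frames)
        assert len(tracks) == 2
        by_pos = {tr.measurements[-1].position: tr for tr in tracks}
        assert by_pos[104].establishment_time == 0
        assert by_pos[112].establishment_time == 1

    def test_gate_limits_linking(self):
        frames = [[self.m(100, 0)], [self.m(400, 1)]]
        tracks = track_backwards(frames)
        assert len(tracks) == 1
        assert tracks[0].establishment_time == 1

    def test_track_conservation(self, groove_spec):
        stack, _ = synthgen.generate_groove_series(groove_spec)
        roi = roi_for(groove_spec)
        frames = [
            gp.measure_frame(stack[k], roi, timepoint=k * 0.5)
            for k in range(stack.shape[0])
        ]
        tracks = track_backwards(frames)
        assert len(tracks) == len(frames[-1])

    def test_empty_final_frame_no_tracks(self):
        assert track_backwards([[self.m(10, 0)], []]) == []


class TestSummaries:
    def test_constant_series_plateaus_immediately(self):
        t = np.arange(10.0)
        assert plateau_time(t, np.full(10, 5.0)) == 0.0

    def test_logistic_series_plateau_matches_analytic_crossing(self):
        r, t0 = 0.5, 8.0
        t = np.arange(72) * 0.5
        values = 80.0 / (1.0 + np.exp(-r * (t - t0)))
        final = values[-1]
        # closed-form time at which the (monotone) logistic crosses 0.9*final
        analytic = t0 - np.log(80.0 / (0.9 * final) - 1.0) / r
        assert plateau_time(t, values) == pytest.approx(analytic, abs=1.0)

    def test_mean_of_two_tracks(self):
        roi = GrooveROI(x0=0, y0=0, x1=500, y1=100, pixel_size=1.0)
        frames = [
            [
                CondensationMeasurement(100, 60.0, 20.0, 1.0, timepoint=0.0),
                CondensationMeasurement(300, 100.0, 20.0, 1.0, timepoint=0.0),
            ]
        ]
        s = gp.summarize_series(frames, np.array([0.0]), roi)
        assert s["mean_length_um"].iloc[0] == pytest.approx(80.0)

    def test_all_missing_metric_warns(self):
        with pytest.warns(UserWarning):
            out = plateau_time(np.arange(3.0), np.full(3, np.nan))
        assert np.isnan(out)


class TestMarkerFraction:
    def build(self, n_marked, n_total, seed=0):
        rng = np.random.default_rng(seed)
        nuclei = np.zeros((100, 100))
        marker = np.zeros((100, 100))
        pos = rng.choice(90, size=(n_total, 2), replace=False) + 5
        for i, (y, x) in enumerate(pos):
            nuclei[y, x] = 1.0
            marker[y, x] = 0.9 if i < n_marked else 0.1
        region = np.ones((100, 100), dtype=bool)
        return nuclei, marker, region

    def test_all_marked(self):
        n, m, r = self.build(10, 10)
        assert gp.marker_positive_fraction(n, m, r, 0.5, detect_threshold=0.5) == 1.0

    def test_none_marked(self):
        n, m, r = self.build(0, 10)
        assert gp.marker_positive_fraction(n, m, r, 0.5, detect_threshold=0.5) == 0.0

    def test_half_marked(self):
        n, m, r = self.build(5, 10)
        assert gp.marker_positive_fraction(n, m, r, 0.5, detect_threshold=0.5) == 0.5

    def test_no_nuclei_warns_nan(self):
        with pytest.warns(UserWarning):
            out = gp.marker_positive_fraction(
                np.zeros((50, 50)), np.zeros((50, 50)), np.ones((50, 50), bool), 0.5,
                detect_threshold=0.5,
            )
        assert np.isnan(out)
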