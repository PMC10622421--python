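"""Kymographs, directionality histograms and the speed conversion."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import capiflow as cf
from capiflow.velocimetry import (
    DirectionHistogram,
    Kymograph,
    build_kymograph,
    direction_histogram,
    smooth_and_peak,
)


def _grating_kymo(theta_deg: float, shape=(128, 128), freq=0.15) -> Kymograph:
    """Sinusoidal grating whose stripes run at theta from the horizontal."""
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    th = math.radians(theta_deg)
    phase = freq * (-math.sin(th) * cols + math.cos(th) * rows)
    return Kymograph(
        data=100.0 + 50.0 * np.sin(2 * np.pi * phase),
        pixel_size_um=4.93,
        frame_rate_fps=58.25,
    )


class TestBuildKymograph:
    def test_stationary_spot_makes_vertical_streak(self, straight_path):
        # a bright non-moving cell: same column bright in every row
        frames = np.full((20, 48, 256, 1), 10.0, dtype=np.float32)
        frames[:, 24, 100, 0] = 200.0
        series = cf.ImageSeries(frames, ["rbc"], 4.93, 58.25)
        kymo = build_kymograph(series, straight_path, "rbc")
        cols = np.argmax(kymo.data, axis=1)
        assert np.all(cols == cols[0])

    def test_moving_spot_argmax_slope(self, straight_path):
        # single spot at 1000 um/s: kymograph argmax advances 3.48 px/frame
        vessel = cf.VesselSpec(
            path=straight_path, mean_speed_um_s=1000.0, spot_rate_per_s=0.1
        )
        spec = cf.SynthSpec(
            image_size=(48, 256), duration_s=0.5, vessels=[vessel], seed=3
        )
        series, truth = cf.render_movie(spec)
        assert truth.counts["count"].max() == 1
        kymo = build_kymograph(series, straight_path, "rbc", 0.0, 0.5)
        cols = np.argmax(kymo.data, axis=1)
        steps = np.diff(cols.astype(float))
        steps = steps[np.abs(steps) < 20]  # drop the wrap-around jump
        assert np.median(steps) == pytest.approx(3.484, abs=0.5)

    def test_constant_image_constant_kymograph(self, straight_path):
        frames = np.full((10, 48, 256, 1), 7.0, dtype=np.float32)
        series = cf.ImageSeries(frames, ["rbc"], 4.93, 58.25)
        kymo = build_kymograph(series, straight_path, "rbc")
        assert np.ptp(kymo.data) == 0.0

    def test_row_count_matches_window(self, clean_movie):
        _, series, _ = clean_movie
        path = cf.VesselPath("v0", "SL", "C", ((8.0, 24.0), (248.0, 24.0)))
        kymo = build_kymograph(series, path, "rbc", 0.0, 1.0)
        assert kymo.n_frames == series.time_to_frame_range(0.0, 1.0)[1]
        assert kymo.n_samples == 240

    def test_short_window_rejected(self, clean_movie):
        _, series, _ = clean_movie
        path = cf.VesselPath("v0", "SL", "C", ((8.0, 24.0), (248.0, 24.0)))
        with pytest.raises(ValueError):
            build_kymograph(series, path, "rbc", 0.0, 0.05)


class TestDirectionHistogram:
    @pytest.mark.parametrize("theta", [30.0, 60.0, 120.0])
    def test_grating_orientation_recovered(self, theta):
        hist = direction_histogram(_grating_kymo(theta), n_bins=90)
        peak_bin = hist.bin_centres_deg[int(np.argmax(hist.weights))]
        assert abs(peak_bin - theta) <= 2.0  # within one 2-degree bin

    def test_vertical_streaks_peak_at_90(self):
        hist = direction_histogram(_grating_kymo(90.0), n_bins=90)
        peak_bin = hist.bin_centres_deg[int(np.argmax(hist.weights))]
        assert abs(peak_bin - 90.0) <= 2.0

    def test_iid_noise_is_flat_and_flagged(self):
        rng = np.random.default_rng(3)
        kymo = Kymograph(rng.normal(100, 5, (128, 128)), 4.93, 58.25)
        coarse = direction_histogram(kymo, n_bins=90)
        assert coarse.weights.max() < 2.0 * np.median(coarse.weights)
        assert coarse.low_structure
        assert direction_histogram(kymo).low_structure  # default binning too

    def test_constant_kymograph_flagged(self):
        kymo = Kymograph(np.full((32, 32), 5.0), 4.93, 58.25)
        assert direction_histogram(kymo).low_structure

    def test_weights_normalised(self):
        hist = direction_histogram(_grating_kymo(45.0))
        assert hist.weights.sum() == pytest.approx(1.0)

    def test_intensity_offset_and_gain_invariance(self, clean_movie):
        _, series, _ = clean_movie
        path = cf.VesselPath("v0", "SL", "C", ((8.0, 24.0), (248.0, 24.0)))
        kymo = build_kymograph(series, path, "rbc", 0.0, 3.0)
        h0 = smooth_and_peak(direction_histogram(kymo))
        import dataclasses

        kymo2 = dataclasses.replace(kymo, data=3.0 * kymo.data + 50.0)
        h1 = smooth_and_peak(direction_histogram(kymo2))
        assert h1.peak_deg == h0.peak_deg


class TestSmoothAndPeak:
    def _hist(self, weights):
        n = len(weights)
        w = np.asarray(weights, float)
        return DirectionHistogram(
            bin_centres_deg=(np.arange(n) + 0.5) * (180.0 / n), weights=w / w.sum()
        )

    def test_unimodal_peak_located(self):
        centres = (np.arange(90) + 0.5) * 2.0
        w = np.exp(-((centres - 16.0) ** 2) / (2 * 6.0**2)) + 1e-4
        hist = self._hist(w)
        out = smooth_and_peak(hist)
        assert out.peak_deg == pytest.approx(16.0, abs=0.2)

    def test_symmetric_mode_at_90(self):
        centres = (np.arange(90) + 0.5) * 2.0
        w = np.exp(-((centres - 90.0) ** 2) / (2 * 10.0**2)) + 1e-4
        out = smooth_and_peak(self._hist(w))
        assert out.peak_deg == pytest.approx(90.0, abs=0.2)

    def test_equal_bimodal_breaks_tie_to_smaller_angle(self):
        centres = (np.arange(90) + 0.5) * 2.0
        w = (
            np.exp(-((centres - 20.0) ** 2) / (2 * 4.0**2))
            + np.exp(-((centres - 160.0) ** 2) / (2 * 4.0**2))
            + 1e-4
        )
        out = smooth_and_peak(self._hist(w))
        assert out.peak_deg == pytest.approx(20.0, abs=0.5)

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError):
            smooth_and_peak(self._hist(np.ones(8)))


class TestAngleToSpeed:
    def test_worked_example(self):
        assert cf.angle_to_speed(16.0, 4.93, 58.25) == pytest.approx(1001.0, abs=1.0)

    def test_45_degrees_equals_p_times_f(self):
        assert cf.angle_to_speed(45.0, 4.93, 58.25) == pytest.approx(
            4.93 * 58.25, abs=1e-9
        )

    def test_vertical_is_stationary(self):
        assert cf.angle_to_speed(90.0, 4.93, 58.25) == 0.0

    def test_angle_folding(self):
        assert cf.angle_to_speed(164.0, 4.93, 58.25) == pytest.approx(
            cf.angle_to_speed(16.0, 4.93, 58.25)
        )

    def test_below_floor_rejected(self):
        with pytest.raises(ValueError, match="measurable"):
            cf.angle_to_speed(0.5, 4.93, 58.25)

    @given(st.floats(min_value=1.5, max_value=90.0))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_conversion_exactness_and_monotonicity(self, theta):
        v = cf.angle_to_speed(theta, 4.93, 58.25)
        if theta < 90.0:
            assert v * math.tan(math.radians(theta)) == pytest.approx(
                4.93 * 58.25, rel=1e-12
            )
        if theta + 1e-3 <= 90.0:  # speed decreases with declination on (0, 90]
            assert cf.angle_to_speed(theta + 1e-3, 4.93, 58.25) < v


class TestWindowedSpeeds:
    def test_thirty_second_series_gives_ten_windows(self):
        # pure bookkeeping: frames of a 30 s acquisition at 58.25 fps
        frames = np.zeros((1747, 8, 16, 1), dtype=np.float32)
        series = cf.ImageSeries(frames, ["rbc"], 4.93, 58.25)
        n_win = series.n_frames // int(math.floor(3.0 * 58.25))
        assert n_win == 10

    def test_five_second_series_gives_one_window(self, straight_path):
        vessel = cf.VesselSpec(
            path=straight_path, mean_speed_um_s=1000.0, spot_rate_per_s=4.0
        )
        spec = cf.SynthSpec(
            image_size=(48, 256), duration_s=5.0, vessels=[vessel], seed=1
        )
        series, _ = cf.render_movie(spec)
        ms = cf.windowed_speeds(
            series, [straight_path], "rbc", window_s=3.0, include_whole_series=False
        )
        assert len(ms) == 1
        assert ms[0].window_index == 1

    def test_constant_speed_recovered_in_every_window(self, noisy_movie):
        _, series, _ = noisy_movie
        path = cf.VesselPath("v0", "SL", "C", ((8.0, 24.0), (248.0, 24.0)))
        ms = cf.windowed_speeds(series, [path], "rbc", window_s=3.0)
        assert all(not m.flags for m in ms)
        for m in ms:
            assert m.speed_um_s == pytest.approx(1000.0, rel=0.1)

    def test_modulated_speeds_track_truth(self, straight_path):
        vessel = cf.VesselSpec(
            path=straight_path, mean_speed_um_s=1000.0, spot_rate_per_s=6.0,
            modulation_amplitude=0.3, modulation_period_s=30.0,
        )
        spec = cf.SynthSpec(
            image_size=(48, 256), duration_s=15.1, vessels=[vessel],
            gaussian_sd=2.0, poisson_scale=1.0, seed=6,
        )
        series, truth = cf.render_movie(spec)
        ms = cf.windowed_speeds(
            series, [straight_path], "rbc", window_s=1.0,
            include_whole_series=False,
        )
        est = np.array([m.speed_um_s for m in ms])
        true = np.array(
            [truth.mean_speed_in_window("v0", m.t0_s, m.t1_s) for m in ms]
        )
        r = np.corrcoef(est, true)[0, 1]
        assert r > 0.7

    def test_series_shorter_than_window(self, straight_path):
        frames = np.zeros((20, 48, 256, 1), dtype=np.float32)
        series = cf.ImageSeries(frames, ["rbc"], 4.93, 58.25)
        with pytest.raises(ValueError):
            cf.windowed_speeds(series, [straight_path], "rbc", window_s=3.0)
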