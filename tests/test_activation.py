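import numpy as np
import pytest

from pacemap import (
    BeatWindow,
    activation_map,
    activation_time_pixel,
    heart_rate,
    leading_site,
    render_movie,
    segment_beats,
    snrt,
)
from pacemap.activation import global_trace
from pacemap.signal_processing import normalize_beats
from pacemap.types import ActivationMap, NormalizedBeat

from conftest import make_config


class TestSegmentBeats:
    def test_five_beats_in_one_second_at_cl_200(self, small_geometry):
        cfg = make_config(
            small_geometry, cl_ms=200.0, n_beats=5, first_firing_ms=0.0
        )
        cfg.duration_ms = 1000.0
        movie, _ = render_movie(cfg)
        trace = global_trace(movie, cfg.geometry.mask)
        windows = segment_beats(trace, movie.frame_rate_hz)
        assert len(windows) == 5

    def test_peak_spacing_matches_ground_truth_cl(self, clean_recording):
        cfg, movie, truth = clean_recording
        trace = global_trace(movie, cfg.geometry.mask)
        windows = segment_beats(trace, movie.frame_rate_hz)
        assert len(windows) == truth.n_beats
        peaks_ms = np.array([w.peak_frame for w in windows]) * movie.frame_interval_ms
        cl = cfg.foci[0].intrinsic_cl_ms["baseline"]
        np.testing.assert_allclose(np.diff(peaks_ms), cl, atol=movie.frame_interval_ms)

    def test_constant_trace_yields_no_beats(self):
        windows = segment_beats(np.zeros(2000), 1000.0)
        assert windows == []

    def test_windows_are_disjoint_and_ordered(self, clean_recording):
        cfg, movie, _ = clean_recording
        trace = global_trace(movie, cfg.geometry.mask)
        windows = segment_beats(trace, movie.frame_rate_hz)
        for a, b in zip(windows[:-1], windows[1:]):
            assert a.end_frame <= b.start_frame


class TestActivationTimePixel:
    def test_linear_ramp_midpoint(self):
        trace = np.linspace(0.0, 1.0, 11)  # 0 -> 1 over 10 ms at 1 kHz
        assert activation_time_pixel(trace, 1000.0) == pytest.approx(5.0)

    def test_linear_interpolation_between_brackets(self):
        trace = np.array([0.0, 0.1, 0.2, 0.4, 0.8, 1.0, 0.9])
        # 0.4 at 3 ms, 0.8 at 4 ms -> 3 + (0.5-0.4)/(0.8-0.4)
        assert activation_time_pixel(trace, 1000.0) == pytest.approx(3.25)

    def test_monotonically_decreasing_trace_is_missing(self):
        trace = np.linspace(1.0, 0.0, 20)
        assert np.isnan(activation_time_pixel(trace, 1000.0))

    def test_crossing_after_peak_ignored(self):
        # the only upward 0.5-crossing happens after the maximum -> missing
        trace = np.array([0.6, 0.9, 0.1, 0.55, 0.5])
        assert np.isnan(activation_time_pixel(trace, 1000.0))


class TestActivationMap:
    def test_matches_ground_truth_up_to_constant_offset(self, clean_recording):
        cfg, movie, truth = clean_recording
        trace = global_trace(movie, cfg.geometry.mask)
        windows = segment_beats(trace, movie.frame_rate_hz)
        beats = normalize_beats(movie, windows, mask=cfg.geometry.mask)
        for b, beat in enumerate(beats):
            amap = activation_map(beat, movie.frame_rate_hz)
            measured = amap.times_ms + beat.window.t_ref_ms
            delta = measured[amap.valid] - truth.true_activation_field[b][amap.valid]
            spread = delta - np.median(delta)
            assert np.abs(spread).max() <= movie.frame_interval_ms

    def test_planar_wave_column_monotone(self):
        t, h, w = 40, 6, 8
        data = np.zeros((t, h, w))
        for c in range(w):
            ramp = np.clip((np.arange(t) - 2 * c) / 10.0, 0.0, 1.0)
            data[:, :, c] = ramp[:, None]
        beat = NormalizedBeat(
            window=BeatWindow(0, t - 1, t - 1, 0.0),
            data=data,
            valid=np.ones((h, w), dtype=bool),
        )
        amap = activation_map(beat, 1000.0)
        assert (np.diff(amap.times_ms, axis=1) > 0).all()

    def test_masked_pixels_invalid(self, clean_recording):
        cfg, movie, _ = clean_recording
        mask = cfg.geometry.mask.copy()
        mask[:3] = False
        trace = global_trace(movie, mask)
        windows = segment_beats(trace, movie.frame_rate_hz)
        beats = normalize_beats(movie, windows, mask=mask)
        amap = activation_map(beats[0], movie.frame_rate_hz)
        assert not amap.valid[:3].any()

    def test_all_invalid_is_error(self):
        data = np.full((10, 3, 3), np.nan)
        beat = NormalizedBeat(
            window=BeatWindow(0, 9, 5, 0.0),
            data=data,
            valid=np.zeros((3, 3), dtype=bool),
        )
        with pytest.raises(ValueError, match="no activation detected"):
            activation_map(beat, 1000.0)


def gradient_map(h=20, w=20, origin=(10, 10), scale=1.0):
    rr, cc = np.mgrid[:h, :w]
    times = scale * np.hypot(rr - origin[0], cc - origin[1])
    return ActivationMap(times_ms=times, valid=np.ones((h, w), dtype=bool))


class TestLeadingSite:
    def test_smooth_wavefront_origin_found(self):
        amap = gradient_map(origin=(7, 12))
        pixel, t = leading_site(amap)
        assert pixel == (7, 12)
        assert t == 0.0

    def test_single_focus_simulation_returns_focus(self, clean_recording):
        cfg, movie, _ = clean_recording
        trace = global_trace(movie, cfg.geometry.mask)
        windows = segment_beats(trace, movie.frame_rate_hz)
        beats = normalize_beats(movie, windows, mask=cfg.geometry.mask)
        for beat in beats:
            amap = activation_map(beat, movie.frame_rate_hz)
            pixel, _ = leading_site(amap)
            assert pixel == cfg.foci[0].position_px

    def test_isolated_early_outlier_rejected(self):
        amap = gradient_map(origin=(15, 15))
        amap.times_ms[2, 2] = amap.times_ms.min() - 50.0  # salt-and-pepper pixel
        pixel, _ = leading_site(amap, neighbor_tolerance_ms=5.0)
        assert pixel == (15, 15)

    def test_cominimal_pixels_merge_by_centroid_rounding(self):
        times = np.full((20, 20), 30.0)
        for p in [(10, 10), (10, 11)]:
            times[p] = 0.0
        # coherent surroundings: neighbors close in time to the minima
        rr, cc = np.mgrid[:20, :20]
        d = np.minimum(np.hypot(rr - 10, cc - 10), np.hypot(rr - 10, cc - 11))
        amap = ActivationMap(times_ms=np.minimum(d * 2.0, 30.0), valid=np.ones((20, 20), bool))
        amap.times_ms[10, 10] = amap.times_ms[10, 11] = 0.0
        pixel, t = leading_site(amap, neighbor_tolerance_ms=6.0)
        assert pixel == (10, 11)  # centroid col 10.5 rounds half away from zero
        assert t == 0.0

    def test_no_coherent_site_is_error(self):
        times = np.array([[0.0, 50.0], [100.0, 150.0]])
        amap = ActivationMap(times_ms=times, valid=np.ones((2, 2), bool))
        with pytest.raises(ValueError, match="no coherent early site"):
            leading_site(amap, neighbor_radius_px=2, neighbor_tolerance_ms=5.0)


class TestHeartRate:
    def win(self, peak):
        return BeatWindow(peak - 10, peak + 10, peak, float(peak - 10))

    @pytest.mark.parametrize(
        "cl_frames,fr,expected",
        [(200, 1000.0, 300.0), (1000, 1000.0, 60.0), (2136, 10000.0, 280.9)],
    )
    def test_rate_from_cycle_length(self, cl_frames, fr, expected):
        windows = [self.win(100 + k * cl_frames) for k in range(4)]
        rates = heart_rate(windows, fr)
        assert rates.shape == (4, 2)
        np.testing.assert_allclose(rates[:, 1], expected, atol=0.05)

    def test_first_beat_carries_following_interval(self):
        windows = [self.win(p) for p in (100, 300, 700)]
        rates = heart_rate(windows, 1000.0)
        np.testing.assert_allclose(rates[:, 0], [200.0, 200.0, 400.0])

    def test_fewer_than_two_beats_empty(self):
        assert heart_rate([self.win(100)], 1000.0).size == 0


class TestSnrt:
    def test_interval_from_last_stimulus(self):
        res = snrt(1200.0, [1500.0, 1800.0])
        assert res.snrt_ms == pytest.approx(300.0)
        assert not res.censored

    def test_no_beat_within_timeout_censored(self):
        res = snrt(1200.0, [9000.0], timeout_ms=3000.0)
        assert res.censored and res.snrt_ms is None
        assert snrt(1200.0, [], timeout_ms=3000.0).censored

    def test_simulated_post_pacing_pause_recovered(self, small_geometry):
        # focus resumes 300 ms after the end of a 12-pulse, 100-ms drive train
        last_stim = 200.0
        cfg = make_config(
            small_geometry, first_firing_ms=last_stim + 300.0, n_beats=3, cl_ms=250.0
        )
        movie, truth = render_movie(cfg)
        trace = global_trace(movie, cfg.geometry.mask)
        windows = segment_beats(trace, movie.frame_rate_hz)
        beats = normalize_beats(movie, windows, mask=cfg.geometry.mask)
        amap = activation_map(beats[0], movie.frame_rate_hz)
        _, t_rel = leading_site(amap)
        first_activation = beats[0].window.t_ref_ms + t_rel
        res = snrt(last_stim, [first_activation])
        # AP50 lags wavefront onset by half the upstroke
        assert res.snrt_ms == pytest.approx(300.0, abs=cfg.template.upstroke_ms)
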