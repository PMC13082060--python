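"""Activity-trace pipeline: extraction, smoothing, baseline, dF/F, filters."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from deep3p.sbr import PhotonCalibration, Roi
from deep3p.traces import (
    ActivityMovie,
    Trace,
    baseline_f0,
    dff,
    extract_trace,
    f0_photon_rate,
    hamming_taps,
    lowpass_hamming,
    median3d_filter,
    process_session,
    temporal_radius_s,
    trim_edges,
)

FS = 6.18


def _movie(frames, fs=FS):
    return ActivityMovie(frames=np.asarray(frames), frame_rate_hz=fs)


def _trace(values, fs=FS, **kw):
    return Trace(values=np.asarray(values, dtype=float), frame_rate_hz=fs, **kw)


class TestExtractTrace:
    def test_constant_movie_sums_roi(self):
        movie = _movie(np.full((5, 10, 10), 3, dtype=int))
        mask = np.zeros((10, 10), bool)
        mask[:10, :10][2:7, 2:7] = True  # 25 px
        trace = extract_trace(movie, Roi.from_mask(mask, label="a"))
        np.testing.assert_allclose(trace.values, 75.0)
        assert trace.n_pixels == 25
        assert trace.roi_label == "a"

    def test_single_pixel_roi_tracks_pixel(self):
        frames = np.zeros((6, 4, 4), int)
        frames[::2, 1, 1] = 1
        mask = np.zeros((4, 4), bool)
        mask[1, 1] = True
        trace = extract_trace(_movie(frames), Roi.from_mask(mask))
        np.testing.assert_array_equal(trace.values, [1, 0, 1, 0, 1, 0])

    def test_out_of_bounds_roi_rejected(self):
        movie = _movie(np.zeros((3, 4, 4), int))
        roi = Roi(kind="mask", coordinates=np.array([[5, 1]]))
        with pytest.raises(ValueError):
            extract_trace(movie, roi)


class TestLowpassHamming:
    def test_window_is_3_taps_at_6hz(self):
        assert len(hamming_taps(0.29, FS)) == 3

    def test_even_round_forced_odd(self):
        assert len(hamming_taps(1.0, 6.0)) == 7  # round(6)=6 -> 7

    def test_unit_dc_gain(self):
        trace = _trace(np.full(50, 12.3))
        out = lowpass_hamming(trace)
        np.testing.assert_allclose(out.values, 12.3, atol=1e-12)

    def test_impulse_response_is_window(self):
        x = np.zeros(21)
        x[10] = 1.0
        out = lowpass_hamming(_trace(x)).values
        w = hamming_taps(0.29, FS)
        np.testing.assert_allclose(out[9:12], w)
        assert out.sum() == pytest.approx(1.0)

    def test_reduces_white_noise_variance(self, rng):
        x = rng.normal(0, 1, 2000)
        out = lowpass_hamming(_trace(x)).values
        assert out.var() < x.var()

    def test_shift_equivariance_away_from_edges(self, rng):
        x = rng.normal(0, 1, 200)
        a = lowpass_hamming(_trace(x)).values
        b = lowpass_hamming(_trace(np.roll(x, 5))).values
        np.testing.assert_allclose(b[10:-10], np.roll(a, 5)[10:-10], atol=1e-12)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            lowpass_hamming(_trace([1.0, 2.0]))


class TestBaseline:
    def test_constant_trace(self):
        assert baseline_f0(_trace(np.full(100, 5.0))) == 5.0

    def test_lower_quintile_of_sparse_activity(self):
        values = np.concatenate([np.zeros(80), np.full(20, 100.0)])
        assert baseline_f0(_trace(values)) == 0.0

    def test_recovers_quiet_baseline_of_clean_trace(self, rng):
        # high-count trace: estimator bias ~1.4 sigma is < 2% of the mean
        base = rng.poisson(10000, 800).astype(float)
        trace = _trace(base)
        assert baseline_f0(trace) == pytest.approx(10000, rel=0.02)

    @given(frac=st.floats(min_value=0.05, max_value=0.9), seed=st.integers(0, 1000))
    def test_never_exceeds_mean(self, frac, seed):
        values = np.random.default_rng(seed).uniform(0, 10, 500)
        assert baseline_f0(_trace(values), frac) <= values.mean()


class TestDff:
    def test_flat_at_baseline_is_zero(self):
        out = dff(_trace(np.full(10, 8.0)), 8.0)
        np.testing.assert_allclose(out.values, 0.0)

    def test_doubling_gives_unity(self):
        out = dff(_trace(np.full(10, 16.0)), 8.0)
        np.testing.assert_allclose(out.values, 1.0)

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError, match="baseline not positive"):
            dff(_trace([1.0, 2.0]), 0.0)


class TestPhotonRate:
    def test_rate_and_fidelity_above_threshold(self):
        trace = _trace(np.full(50, 30.0))
        rate, ok = f0_photon_rate(trace)
        assert rate == pytest.approx(30 * FS)  # 185.4 photons/s
        assert ok

    def test_boundary_below_threshold(self):
        rate, ok = f0_photon_rate(_trace(np.full(50, 24.0)))
        assert rate == pytest.approx(148.32, abs=0.01)
        assert not ok

    def test_zero_baseline(self):
        rate, ok = f0_photon_rate(_trace(np.zeros(50)))
        assert rate == 0.0 and not ok

    def test_calibration_applied(self):
        trace = _trace(np.full(50, 10.0))
        rate, _ = f0_photon_rate(trace, PhotonCalibration(conversion_factor=3.0))
        assert rate == pytest.approx(30 * FS)


class TestMedianFilter:
    def test_constant_movie_unchanged(self):
        movie = _movie(np.full((40, 6, 6), 9, dtype=np.uint16), fs=FS)
        out = median3d_filter(movie, rt=18)
        np.testing.assert_array_equal(out.frames, movie.frames)
        assert out.frames.dtype == movie.frames.dtype

    def test_salt_impulse_removed(self):
        frames = np.full((20, 6, 6), 5, dtype=int)
        frames[10, 3, 3] = 500
        out = median3d_filter(_movie(frames), rt=5)
        assert out.frames[10, 3, 3] == 5

    def test_default_radius_spans_about_3s(self):
        assert temporal_radius_s(18, FS) == pytest.approx(2.91, abs=0.01)

    def test_too_short_movie_rejected(self):
        with pytest.raises(ValueError):
            median3d_filter(_movie(np.zeros((10, 4, 4), int)), rt=18)


class TestTrimEdges:
    def test_drops_9_each_side(self):
        out = trim_edges(_movie(np.zeros((100, 4, 4), int)), 9)
        assert out.n_frames == 82

    def test_zero_is_identity(self):
        movie = _movie(np.zeros((10, 4, 4), int))
        assert trim_edges(movie, 0) is movie

    def test_exhausted_movie_rejected(self):
        with pytest.raises(ValueError):
            trim_edges(_movie(np.zeros((18, 4, 4), int)), 9)


class TestProcessSession:
    def _session(self, rng, n_rois=3):
        frames = rng.poisson(30.0, (120, 20, 20)).astype(np.uint16)
        movie = _movie(frames)
        rois = []
        for i in range(n_rois):
            mask = np.zeros((20, 20), bool)
            mask[i * 6: i * 6 + 5, 2:7] = True
            rois.append(Roi.from_mask(mask, label=f"n{i}"))
        return movie, rois

    def test_one_row_per_roi_with_metadata(self, rng):
        movie, rois = self._session(rng)
        table = process_session(movie, rois)
        assert list(table["label"]) == ["n0", "n1", "n2"]
        assert (table["n_pixels"] == 25).all()
        assert len(table["dff"].iloc[0]) == movie.n_frames

    def test_zero_rois_empty_table(self, rng):
        movie, _ = self._session(rng)
        table = process_session(movie, [])
        assert len(table) == 0
        assert "fidelity" in table.columns

    def test_bright_session_flags_fidelity(self, rng):
        movie, rois = self._session(rng)  # 25 px x 30 counts -> ~4600 ph/s
        table = process_session(movie, rois)
        assert table["fidelity"].all()

    def test_discard_initial_drops_frames(self, rng):
        movie, rois = self._session(rng)
        table = process_session(movie, rois, discard_initial_s=2.0)
        expected = movie.n_frames - int(round(2.0 * FS))
        assert len(table["trace"].iloc[0]) == expected

    def test_normalize_order_switch_runs(self, rng):
        movie, rois = self._session(rng)
        table = process_session(movie, rois, filter_before_normalize=False)
        assert len(table) == 3
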