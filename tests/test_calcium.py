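"""Grid-ROI calcium pipeline: normalization, tiling, dF, indices, phases."""

from __future__ import annotations

import numpy as np
import pytest

from spinalrhythm import calcium as ca
from spinalrhythm.bursts import BurstEvent
from spinalrhythm.core import CalciumMovie
from spinalrhythm.synth import generate_calcium_movie

IDENTITY_LANDMARKS = {
    "cc_row": 200.0, "cc_col": 249.5, "left_col": 0.0, "right_col": 499.0,
    "dorsal_row": 0.0, "ventral_row": 399.0,
}


class TestNormalizeField:
    def test_output_dimensions(self, small_movie):
        movie, _ = small_movie
        norm = ca.normalize_field(movie)
        assert norm.frames.shape[1:] == (400, 500)
        assert norm.normalized

    def test_identity_on_prenormalized_movie(self):
        rng = np.random.default_rng(0)
        frames = rng.random((3, 400, 500), dtype=np.float32)
        movie = CalciumMovie(frames=frames, fs=10.0, landmarks=IDENTITY_LANDMARKS)
        norm = ca.normalize_field(movie)
        np.testing.assert_allclose(norm.frames, frames, atol=1e-6)

    def test_left_edge_point_maps_to_column_zero(self):
        frames = np.zeros((2, 100, 120), dtype=np.float32)
        lm = {"cc_row": 50.0, "cc_col": 70.0, "left_col": 10.0, "right_col": 110.0,
              "dorsal_row": 5.0, "ventral_row": 95.0}
        frames[:, 50, 10] = 100.0  # point source on the left edge
        movie = CalciumMovie(frames=frames, fs=10.0, landmarks=lm)
        norm = ca.normalize_field(movie)
        col = np.argmax(norm.frames[0].max(axis=0))
        assert col <= 1

    def test_canal_column_is_midline(self):
        frames = np.zeros((2, 100, 120), dtype=np.float32)
        lm = {"cc_row": 50.0, "cc_col": 70.0, "left_col": 10.0, "right_col": 110.0,
              "dorsal_row": 5.0, "ventral_row": 95.0}
        frames[:, :, 70] = 50.0  # bright stripe through the canal column
        movie = CalciumMovie(frames=frames, fs=10.0, landmarks=lm)
        norm = ca.normalize_field(movie)
        col = np.argmax(norm.frames[0].mean(axis=0))
        assert abs(col - 249.5) <= 1.0

    def test_degenerate_landmarks_rejected(self):
        frames = np.zeros((2, 100, 120), dtype=np.float32)
        lm = dict(IDENTITY_LANDMARKS, cc_col=0.0, right_col=110.0, cc_row=50.0,
                  ventral_row=95.0)
        movie = CalciumMovie(frames=frames, fs=10.0, landmarks=lm)
        with pytest.raises(ValueError):
            ca.normalize_field(movie)


class TestBuildGrid:
    def test_500_rois_250_per_side(self, grid):
        assert len(grid.ids) == 500
        assert np.sum(grid.sides == "right") == 250
        assert np.sum(grid.sides == "left") == 250
        assert set(grid.ids) == set(range(1, 501))
        # right half carries ids 1-250
        assert set(grid.ids[grid.sides == "right"]) == set(range(1, 251))

    def test_tiling_is_disjoint_and_covering(self, grid):
        cover = np.zeros((400, 500), dtype=int)
        for r0, r1, c0, c1 in grid.footprints:
            cover[r0:r1, c0:c1] += 1
        assert np.all(cover == 1)

    def test_wrong_field_size_rejected(self):
        with pytest.raises(ValueError):
            ca.build_grid((400, 400))


def _flat_movie(value=5.0, T=150):
    frames = np.full((T, 400, 500), value, dtype=np.float32)
    return CalciumMovie(frames=frames, fs=10.0, landmarks=IDENTITY_LANDMARKS,
                        normalized=True)


class TestExtractDeltaF:
    def test_constant_movie_gives_zero_df(self, grid):
        ts = ca.extract_delta_f(_flat_movie(), grid)
        np.testing.assert_array_equal(ts.traces, 0.0)
        assert not ts.normalized  # zero global max cannot be a divisor

    def test_df_definition_pre_normalization(self, grid):
        movie = _flat_movie(10.0, T=150)
        movie.frames[40] = 12.0  # one bright frame outside the baseline block
        ts = ca.extract_delta_f(movie, grid)
        # normalized: the bright frame is the global max, so it reads 1.0
    # everywhere and dF is 2.0 / 2.0 pre-division
        assert ts.global_max == pytest.approx(2.0)
        np.testing.assert_allclose(ts.traces[:, 40], 1.0)

    def test_normalized_max_is_one(self, small_movie_maps):
        movie, _, ts, _, _ = small_movie_maps
        # the filtered traces are re-centred; check the invariant on a fresh
        # unfiltered extraction
        norm = ca.normalize_field(movie)
        raw_ts = ca.extract_delta_f(norm, ca.build_grid())
        assert raw_ts.normalized
        assert raw_ts.traces.max() == pytest.approx(1.0)

    def test_intensity_scaling_invariance(self):
        movie, _ = generate_calcium_movie(duration_s=30, shape=(60, 80),
                                          noise_sd=0.0, seed=0)
        grid = ca.build_grid()
        ts1 = ca.extract_delta_f(ca.normalize_field(movie), grid)
        scaled = movie.with_frames(movie.frames * 3.0)
        ts2 = ca.extract_delta_f(ca.normalize_field(scaled), grid)
        assert ts2.global_max == pytest.approx(3.0 * ts1.global_max, rel=1e-5)
        np.testing.assert_allclose(ts2.traces, ts1.traces, atol=1e-5)

    def test_tiling_conservation(self, grid):
        rng = np.random.default_rng(2)
        frames = rng.random((120, 400, 500), dtype=np.float32)
        movie = CalciumMovie(frames=frames, fs=10.0,
                             landmarks=IDENTITY_LANDMARKS, normalized=True)
        ts = ca.extract_delta_f(movie, grid, n_baseline_frames=100)
        # mean of ROI means equals the whole-field mean per frame (equal-area tiles)
        f_t = np.array([frames[:, r0:r1, c0:c1].mean(axis=(1, 2))
                        for r0, r1, c0, c1 in grid.footprints])
        np.testing.assert_allclose(f_t.mean(axis=0), frames.mean(axis=(1, 2)),
                                   rtol=1e-5)

    def test_too_few_frames_rejected(self, grid):
        with pytest.raises(ValueError):
            ca.extract_delta_f(_flat_movie(T=80), grid)


class TestPreprocessTraces:
    def _traceset(self, traces, fs=10.0):
        grid = ca.build_grid()
        n = traces.shape[0]
        full = np.zeros((500, traces.shape[1]))
        full[:n] = traces
        return ca.ROITraceSet(traces=full, fs=fs, grid=grid,
                              f0=np.zeros(500), global_max=1.0, normalized=True)

    def test_passband_amplitude_preserved(self):
        t = np.arange(1800) / 10.0
        x = np.sin(2 * np.pi * 0.4 * t)
        out = ca.preprocess_traces(self._traceset(x[None, :])).traces[0]
        mid = out[200:-200]
        assert mid.max() == pytest.approx(1.0, rel=0.02)

    def test_stopband_attenuated(self):
        t = np.arange(1800) / 10.0
        x = np.sin(2 * np.pi * 4.9 * t)
        out = ca.preprocess_traces(self._traceset(x[None, :])).traces[0]
        assert np.abs(out).max() < 0.1 * 1.0

    def test_constant_trace_maps_to_zero(self):
        x = np.full((1, 600), 3.3)
        out = ca.preprocess_traces(self._traceset(x)).traces[0]
        np.testing.assert_allclose(out, 0.0, atol=1e-9)

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            ca.preprocess_traces(self._traceset(np.zeros((1, 100))), lowpass_hz=6.0)


class TestOscillationIndex:
    def test_pure_sinusoid_approaches_two(self):
        fs, f = 10.0, 0.4
        t = np.arange(1800) / fs
        x = np.sin(2 * np.pi * f * t)
        idx = ca.oscillation_index(x, fs, expected_period=1 / f)
        assert idx == pytest.approx(2.0, abs=0.05)

    def test_white_noise_near_zero(self):
        fs = 10.0
        rng = np.random.default_rng(0)
        vals = [ca.oscillation_index(rng.normal(size=1800), fs, 2.5)
                for _ in range(10)]
        assert np.mean(vals) < 0.1

    def test_monotone_in_snr(self):
        fs, f = 10.0, 0.4
        t = np.arange(1800) / fs
        sig = np.sin(2 * np.pi * f * t)
        rng = np.random.default_rng(1)
        noise = rng.normal(size=1800)
        idxs = [ca.oscillation_index(a * sig + noise, fs, 1 / f)
                for a in (0.0, 0.5, 1.0, 2.0, 8.0)]
        assert all(b >= a - 0.05 for a, b in zip(idxs, idxs[1:]))
        assert idxs[-1] > idxs[0] + 0.5

    def test_bounds(self):
        fs = 10.0
        rng = np.random.default_rng(2)
        for _ in range(5):
            idx = ca.oscillation_index(rng.normal(size=900), fs, 2.5)
            assert 0.0 <= idx <= 2.0

    def test_too_short_trace_rejected(self):
        with pytest.raises(ValueError):
            ca.oscillation_index(np.zeros(100), 10.0, expected_period=2.5)


class TestMaps:
    def test_normalize_index_map_shared_divisor(self, grid):
        raw = np.zeros(500)
        raw[429] = 1.6       # strongest ROI, left half (id 430)
        raw[grid.ids == 10] = 0.8
        omap = ca.normalize_index_map(raw, grid)
        assert omap.normalized_values[429] == pytest.approx(1.0)
        left = omap.normalized_values[grid.sides == "left"]
        right = omap.normalized_values[grid.sides == "right"]
        # one global divisor: the weaker half's maximum stays below 1
        assert right.max() == pytest.approx(0.5)
        assert left.max() == pytest.approx(1.0)

    def test_uniform_map_normalizes_to_one(self, grid):
        omap = ca.normalize_index_map(np.full(500, 0.7), grid)
        np.testing.assert_allclose(omap.normalized_values, 1.0)

    def test_all_zero_map_flagged(self, grid):
        omap = ca.normalize_index_map(np.zeros(500), grid)
        assert omap.all_zero
        np.testing.assert_array_equal(omap.normalized_values, 0.0)

    def test_reference_is_argmax_of_average(self, grid):
        a = np.zeros(500); a[10] = 1.0; a[20] = 0.8
        b = np.zeros(500); b[10] = 0.2; b[20] = 1.0
        m1 = ca.normalize_index_map(a, grid)
        m2 = ca.normalize_index_map(b, grid)
        avg, ref = ca.average_maps_and_reference([m1, m2])
        # mean map peaks at index 20, not at either input's own argmax
        assert ref == int(grid.ids[20])
        single, ref1 = ca.average_maps_and_reference([m1])
        assert ref1 == int(grid.ids[10])

    def test_construction_with_known_strongest_roi(self, grid):
        rng = np.random.default_rng(3)
        target = int(np.flatnonzero(grid.ids == 430)[0])
        maps = []
        for _ in range(3):
            raw = rng.uniform(0, 0.5, 500)
            raw[target] = 1.5
            maps.append(ca.normalize_index_map(raw, grid))
        _, ref = ca.average_maps_and_reference(maps)
        assert ref == 430

    def test_mismatched_grids_rejected(self, grid):
        m = ca.normalize_index_map(np.ones(500), grid)
        other = ca.ROIGrid(footprints=grid.footprints[::-1].copy(),
                           ids=grid.ids.copy(), sides=grid.sides.copy())
        m2 = ca.normalize_index_map(np.ones(500), other)
        with pytest.raises(ValueError):
            ca.average_maps_and_reference([m, m2])


def _traceset_from(traces, fs=10.0):
    grid = ca.build_grid()
    full = np.zeros((500, traces.shape[1]))
    full[:traces.shape[0]] = traces
    return ca.ROITraceSet(traces=full, fs=fs, grid=grid, f0=np.zeros(500),
                          global_max=1.0, normalized=True, filtered=True)


class TestPhaseMap:
    def test_reference_phase_zero_and_delay_quarter(self):
        fs, f = 10.0, 0.4
        t = np.arange(1800) / fs
        ref = np.sin(2 * np.pi * f * t)
        quarter = np.sin(2 * np.pi * f * (t - 0.25 / f))
        ts = _traceset_from(np.stack([ref, quarter]))
        pmap = ca.phase_map(ts, reference_roi=int(ts.grid.ids[0]), cycle_period=1 / f)
        assert pmap.phases[0] == 0.0
        assert pmap.phases[1] == pytest.approx(0.25, abs=0.02)

    def test_phase_additivity_under_imposed_delay(self):
        fs, f = 10.0, 0.4
        t = np.arange(1800) / fs
        ref = np.sin(2 * np.pi * f * t)
        rows = [ref]
        deltas = [0.3, 0.7, 1.1]
        for d in deltas:
            rows.append(np.sin(2 * np.pi * f * (t - d)))
        ts = _traceset_from(np.stack(rows))
        pmap = ca.phase_map(ts, int(ts.grid.ids[0]), cycle_period=1 / f)
        for i, d in enumerate(deltas, start=1):
            expected = (d * f) % 1.0
            diff = (pmap.phases[i] - expected + 0.5) % 1.0 - 0.5
            assert abs(diff) < 0.02

    def test_flat_trace_gives_nan_not_zero(self):
        fs, f = 10.0, 0.4
        t = np.arange(900) / fs
        ref = np.sin(2 * np.pi * f * t)
        ts = _traceset_from(np.stack([ref, np.zeros_like(ref)]))
        pmap = ca.phase_map(ts, int(ts.grid.ids[0]), cycle_period=1 / f)
        assert np.isnan(pmap.phases[1])


class TestEndToEnd:
    def test_antiphase_movie_phases_bimodal_at_zero_and_half(self, small_movie_maps):
        movie, truth, ts, omap, pmap = small_movie_maps
        grid = omap.grid
        ref_side = grid.sides[grid.ids == omap.reference_roi][0]
        strong = omap.normalized_values > 0.5
        contra = strong & (grid.sides != ref_side)
        ipsi = strong & (grid.sides == ref_side)
        assert contra.sum() >= 5 and ipsi.sum() >= 5
        contra_dev = np.abs((pmap.phases[contra] - 0.5 + 0.5) % 1.0 - 0.5)
        ipsi_dev = np.abs((pmap.phases[ipsi] + 0.5) % 1.0 - 0.5)
        assert np.median(contra_dev) < 0.05
        assert np.median(ipsi_dev) < 0.05

    def test_no_oscillators_gives_near_zero_map(self):
        movie, _ = generate_calcium_movie(duration_s=60, shape=(60, 80),
                                          oscillators=[], noise_sd=1.0,
                                          background=100.0, seed=5)
        norm = ca.normalize_field(movie)
        grid = ca.build_grid()
        ts = ca.preprocess_traces(ca.extract_delta_f(norm, grid))
        raw = ca.oscillation_map(ts, expected_period=2.5)
        # the lower-lumbar situation: no rhythmic sources, indices next to zero
        assert np.median(raw) < 0.3

    def test_root_phase_comparison_ipsi_in_phase_contra_anti(self, small_movie_maps):
        movie, truth, ts, omap, pmap = small_movie_maps
        period = 1.0 / truth.movie_frequency
        onsets = np.arange(0.0, movie.duration - period, period)
        ipsi_events = [BurstEvent(o, o + 0.3 * period, o + 0.1, 1.0, 0.0)
                       for o in onsets]
        contra_events = [BurstEvent(o + period / 2, o + period / 2 + 0.3 * period,
                                    o + period / 2 + 0.1, 1.0, 0.0) for o in onsets]
        phases = ca.root_phase_comparison(
            ts, {"left_root": ipsi_events, "right_root": contra_events}, period)
        grid = ts.grid
        strong = omap.normalized_values > 0.5
        left_osc = strong & (grid.sides == "left")
        # left-side oscillators follow the left root's timing, delayed only by
        # the indicator-decay lag (~tau / period of the cycle); the contra root
        # sits half a cycle further
        kernel_lag = truth.decay_tau / period
        dev_ipsi = np.abs((phases["left_root"][left_osc] + 0.5) % 1.0 - 0.5)
        dev_contra = np.abs((phases["right_root"][left_osc] - 0.5 + 0.5) % 1.0 - 0.5)
        assert np.median(dev_ipsi) < kernel_lag
        assert np.median(dev_contra) < kernel_lag
        sep = (phases["right_root"][left_osc] - phases["left_root"][left_osc]) % 1.0
        assert np.median(np.abs(sep - 0.5)) < 0.02

    def test_root_phase_requires_overlap(self, small_movie_maps):
        _, truth, ts, _, _ = small_movie_maps
        late = [BurstEvent(1000.0, 1001.0, 1000.5, 1.0, 0.0)]
        with pytest.raises(ValueError):
            ca.root_phase_comparison(ts, {"root": late}, 2.5)
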