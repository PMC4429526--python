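"""Imaging chain: baseline model, CTA, SD image, ROI discovery, PSD gate."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chemoreflex import imaging, synthgen
from chemoreflex.imaging import (
    CellTrace,
    FrameStack,
    ImagingParams,
    compute_dff,
    cycle_triggered_average,
    detect_cycles,
    detect_rtn_cells,
    extract_traces,
    iterative_threshold_rois,
    photostim_response_map,
    sd_image,
    validate_rhythmic,
)


def single_pixel_stack(values, frame_rate=10.0):
    return FrameStack(np.asarray(values, dtype=float).reshape(-1, 1, 1), frame_rate)


class TestComputeDff:
    def test_constant_stack_gives_zero(self):
        stack = FrameStack(np.full((50, 4, 4), 100.0), 10.0)
        d = compute_dff(stack, w=10)
        assert d.data.shape == (40, 4, 4)
        assert np.allclose(d.data, 0.0)

    def test_output_length_is_t_minus_w(self):
        stack = FrameStack(np.random.default_rng(0).uniform(50, 60, (300, 2, 2)), 10.0)
        assert compute_dff(stack, w=100).n_frames == 200

    def test_hand_computed_forward_mean(self):
        # F = [1, 2, 3, 4], w = 2: F0 = [1.5, 2.5]; dF/F = [-1/3, -1/5]
        d = compute_dff(single_pixel_stack([1, 2, 3, 4]), w=2)
        assert d.data.ravel() == pytest.approx([-1 / 3, -1 / 5])

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        F = rng.uniform(10, 20, (60, 3, 3))
        a = compute_dff(FrameStack(F, 10.0), w=20)
        b = compute_dff(FrameStack(7.3 * F, 10.0), w=20)
        assert np.allclose(a.data, b.data)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            compute_dff(single_pixel_stack([1, 2, 3]), w=5)

    def test_nonpositive_baseline_masked_or_raised(self):
        stack = single_pixel_stack([1.0, -2.0, -2.0, 1.0, 1.0])
        d = compute_dff(stack, w=2)
        assert np.isnan(d.data[0, 0, 0])  # F0 of frames 1,2 is negative
        with pytest.raises(ValueError):
            compute_dff(stack, w=2, nonpositive="raise")

    @given(t=st.integers(5, 60), w=st.integers(1, 4))
    @settings(max_examples=20, deadline=None)
    def test_length_property(self, t, w):
        stack = single_pixel_stack(np.linspace(10, 20, t))
        assert compute_dff(stack, w=w).n_frames == t - w


class TestDetectCycles:
    def test_sinusoid_peak_count(self):
        fr = 10.0
        t = np.arange(0, 60, 1 / fr)
        trace = CellTrace(0, np.sin(2 * np.pi * 0.2 * t), fr)
        events = detect_cycles(trace, min_separation=2.5)
        assert len(events) == 12

    def test_constant_trace_has_no_events(self):
        trace = CellTrace(0, np.ones(100), 10.0)
        assert len(detect_cycles(trace, min_separation=1.0)) == 0

    def test_synthetic_cell_event_count_near_ground_truth(self):
        spec = synthgen.MovieSpec(
            height=24,
            width=24,
            n_frames=1800,
            cells=(synthgen.CellSpec((12, 12), 2.0, 0.2, 0.5),),
            seed=3,
        )
        stack, gt = synthgen.generate_calcium_movie(spec)
        dff = compute_dff(stack)
        trace = CellTrace(0, np.nanmean(dff.data, axis=(1, 2)), dff.frame_rate)
        events = detect_cycles(trace, min_separation=2.5)
        # the dropped baseline tail removes up to w/frame_rate * f events
        planted_in_range = np.sum(gt.event_times[0] < dff.n_frames / dff.frame_rate)
        assert abs(len(events) - planted_in_range) <= 1


class TestCycleTriggeredAverage:
    def test_periodic_stack_recovers_one_cycle(self):
        fr = 10.0
        period = 20  # frames
        t = np.arange(400)
        cycle = np.sin(2 * np.pi * t / period)
        data = np.tile(cycle[:, None, None], (1, 2, 2))
        dff = imaging.DFFSeries(data=data, w=0, frame_rate=fr)
        events = (np.arange(5, 395, period)) / fr
        cta = cycle_triggered_average(dff, events, window=(5, 15))
        assert cta.data.shape == (20, 2, 2)
        expected = np.sin(2 * np.pi * np.arange(20) / period)
        assert np.allclose(cta.data[:, 0, 0], expected, atol=1e-12)

    def test_noise_averaging_shrinks_sd(self):
        rng = np.random.default_rng(0)
        fr = 10.0
        data = rng.normal(0, 1, (2000, 4, 4))
        dff = imaging.DFFSeries(data=data, w=0, frame_rate=fr)
        n = 64
        events = (np.arange(10, 10 + 30 * n, 30)) / fr
        cta = cycle_triggered_average(dff, events, window=(5, 5))
        ratio = cta.data.std() / data.std()
        assert ratio == pytest.approx(1 / math.sqrt(n), rel=0.25)

    def test_single_event_rejected(self):
        dff = imaging.DFFSeries(data=np.zeros((50, 2, 2)), w=0, frame_rate=10.0)
        with pytest.raises(ValueError):
            cycle_triggered_average(dff, [2.0], window=(5, 5))

    def test_clipped_events_skipped_and_counted(self):
        dff = imaging.DFFSeries(data=np.zeros((50, 2, 2)), w=0, frame_rate=10.0)
        cta = cycle_triggered_average(dff, [0.1, 2.0, 3.0, 4.9], window=(5, 5))
        assert cta.n_events == 2


class TestSdImage:
    def test_constant_series_is_zero(self):
        assert np.allclose(sd_image(np.full((10, 3, 3), 4.2)), 0.0, atol=1e-12)

    def test_alternating_pixel_population_sd_is_one(self):
        data = np.zeros((8, 1, 1))
        data[::2] = 1.0
        data[1::2] = -1.0
        assert sd_image(data)[0, 0] == pytest.approx(1.0)

    def test_offset_invariance(self):
        rng = np.random.default_rng(2)
        data = rng.normal(0, 1, (30, 4, 4))
        assert np.allclose(sd_image(data), sd_image(data + 17.0))

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            sd_image(np.zeros((1, 3, 3)))

    def test_planted_cells_are_local_maxima(self, twenty_cell_movie):
        _, stack, gt = twenty_cell_movie
        dff = compute_dff(stack)
        sd = sd_image(dff)
        for cell in gt.cells[:5]:
            r, c = (int(round(v)) for v in cell.center)
            neighborhood = sd[r - 4 : r + 5, c - 4 : c + 5]
            # the cell center dominates its neighborhood and the background
            assert sd[r, c] > 3 * np.median(sd)
            assert sd[r, c] >= 0.9 * neighborhood.max()


def _oracle_iterative_threshold(img, min_area, max_area, start_quantile, step, stop_mad_k):
    """Independent pure-python oracle: BFS flood fill at each threshold with
    the same acceptance, skirt-suppression and zero-out rules."""
    img = [row[:] for row in img.tolist()]
    H, W = len(img), len(img[0])
    flat = sorted(v for row in img for v in row)
    med = flat[len(flat) // 2] if len(flat) % 2 else 0.5 * (
        flat[len(flat) // 2 - 1] + flat[len(flat) // 2]
    )
    devs = sorted(abs(v - med) for row in img for v in row)
    mad = devs[len(devs) // 2] if len(devs) % 2 else 0.5 * (
        devs[len(devs) // 2 - 1] + devs[len(devs) // 2]
    )
    stop = med + stop_mad_k * mad
    thresh = float(np.quantile(np.asarray(flat), start_quantile))
    claimed = [[False] * W for _ in range(H)]
    removed = [[False] * W for _ in range(H)]
    rois = []
    while thresh > stop:
        seen = [[False] * W for _ in range(H)]
        for r0 in range(H):
            for c0 in range(W):
                if seen[r0][c0] or removed[r0][c0] or img[r0][c0] <= thresh:
                    continue
                comp = []
                queue = [(r0, c0)]
                seen[r0][c0] = True
                while queue:
                    r, c = queue.pop()
                    comp.append((r, c))
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if (
                                0 <= rr < H
                                and 0 <= cc < W
                                and not seen[rr][cc]
                                and not removed[rr][cc]
                                and img[rr][cc] > thresh
                            ):
                                seen[rr][cc] = True
                                queue.append((rr, cc))
                if not (min_area <= len(comp) <= max_area):
                    continue
                touches = any(
                    claimed[min(max(r + dr, 0), H - 1)][min(max(c + dc, 0), W - 1)]
                    for r, c in comp
                    for dr in (-1, 0, 1)
                    for dc in (-1, 0, 1)
                )
                if touches:
                    continue
                rois.append(frozenset(comp))
                for r, c in comp:
                    claimed[r][c] = True
                    removed[r][c] = True
        thresh *= step
    return rois


class TestIterativeThresholdRois:
    def _blob_image(self, centers, sigma=2.0, shape=(32, 32), amp=10.0):
        rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
        img = np.zeros(shape)
        for r0, c0 in centers:
            img += amp * np.exp(-((rows - r0) ** 2 + (cols - c0) ** 2) / (2 * sigma**2))
        return img

    def test_two_blobs_found_at_their_centers(self):
        img = self._blob_image([(8, 8), (24, 22)])
        rois = iterative_threshold_rois(img, min_area=3, max_area=120)
        assert len(rois) == 2
        centroids = sorted(r.centroid for r in rois)
        assert centroids[0] == pytest.approx((8, 8), abs=1.0)
        assert centroids[1] == pytest.approx((24, 22), abs=1.0)

    def test_flat_image_yields_nothing(self):
        assert iterative_threshold_rois(np.ones((16, 16))) == []

    def test_blob_below_min_area_rejected(self):
        # realistic noise floor keeps the stop threshold meaningful, so the
        # tiny blob never reaches the minimum area
        rng = np.random.default_rng(3)
        img = self._blob_image([(16, 16)], sigma=0.6) + np.abs(rng.normal(0, 0.05, (32, 32)))
        assert iterative_threshold_rois(img, min_area=30, max_area=200) == []

    def test_rois_are_disjoint(self):
        rng = np.random.default_rng(4)
        img = self._blob_image([(8, 8), (20, 24), (26, 8)]) + rng.normal(0, 0.1, (32, 32))
        rois = iterative_threshold_rois(img, min_area=3, max_area=200)
        seen = set()
        for roi in rois:
            assert not (set(roi.pixels) & seen)
            seen |= set(roi.pixels)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        img = self._blob_image(
            [(rng.uniform(6, 26), rng.uniform(6, 26)) for _ in range(3)],
            sigma=rng.uniform(1.2, 2.5),
        ) + rng.normal(0, 0.2, (32, 32))
        kwargs = dict(min_area=3, max_area=150, start_quantile=0.99, step=0.9, stop_mad_k=2.0)
        fast = iterative_threshold_rois(img, **kwargs)
        slow = _oracle_iterative_threshold(img, **kwargs)
        assert {frozenset(r.pixels) for r in fast} == set(slow)


class TestExtractTraces:
    def test_single_pixel_roi_equals_pixel_series(self):
        data = np.random.default_rng(0).normal(0, 1, (30, 5, 5))
        dff = imaging.DFFSeries(data=data, w=0, frame_rate=10.0)
        roi = imaging.ROI(label=1, pixels=((2, 3),), centroid=(2, 3), area=1)
        (trace,) = extract_traces(dff, [roi])
        assert np.allclose(trace.values, data[:, 2, 3])

    def test_uniform_frames_give_uniform_trace(self):
        data = np.arange(20, dtype=float)[:, None, None] * np.ones((1, 4, 4))
        dff = imaging.DFFSeries(data=data, w=0, frame_rate=10.0)
        roi = imaging.ROI(label=1, pixels=((0, 0), (1, 1), (3, 2)), centroid=(1, 1), area=3)
        (trace,) = extract_traces(dff, [roi])
        assert np.allclose(trace.values, np.arange(20))

    def test_out_of_bounds_roi_named_in_error(self):
        dff = imaging.DFFSeries(data=np.zeros((10, 4, 4)), w=0, frame_rate=10.0)
        roi = imaging.ROI(label=7, pixels=((5, 1),), centroid=(5, 1), area=1)
        with pytest.raises(ValueError, match="7"):
            extract_traces(dff, [roi])

    def test_planted_amplitude_recovered_noiselessly(self):
        # sparse bursts (0.1 Hz, tau 0.5 s) keep the mean activity small so
        # the forward running baseline barely attenuates the transient peak
        spec = synthgen.MovieSpec(
            height=24,
            width=24,
            n_frames=900,
            cells=(synthgen.CellSpec((12, 12), 2.0, 0.1, 0.5, burst_decay_tau=0.5),),
            noise_sd=0.0,
            seed=0,
        )
        stack, gt = synthgen.generate_calcium_movie(spec)
        dff = compute_dff(stack)
        # the center pixel carries the full planted amplitude
        roi = imaging.ROI(label=1, pixels=((12, 12),), centroid=(12, 12), area=1)
        (trace,) = extract_traces(dff, [roi])
        peak = np.nanmax(trace.values)
        assert peak == pytest.approx(0.5, rel=0.2)


class TestValidateRhythmic:
    @staticmethod
    def tone_trace(freq, fr=10.0, duration=180.0):
        t = np.arange(0, duration, 1 / fr)
        return CellTrace(0, np.sin(2 * np.pi * freq * t), fr)

    def test_in_band_tone_accepted_with_accurate_peak(self):
        cls = validate_rhythmic(self.tone_trace(0.2))
        assert cls.accepted
        assert abs(cls.peak_frequency - 0.2) <= 0.025  # one Welch bin

    @pytest.mark.parametrize("freq", [0.05, 0.5])
    def test_out_of_band_tone_rejected(self, freq):
        assert not validate_rhythmic(self.tone_trace(freq)).accepted

    def test_tone_sweep_gate(self):
        # bin width is 0.025 Hz for 40 s segments at 10 Hz sampling
        for freq in np.arange(0.025, 1.001, 0.025):
            cls = validate_rhythmic(self.tone_trace(float(freq)))
            assert cls.accepted == (0.1 <= freq <= 0.4), f"{freq} Hz misgated"
            assert abs(cls.peak_frequency - freq) <= 0.025

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError, match="short"):
            validate_rhythmic(self.tone_trace(0.2, duration=10.0))


class TestDetectRtnCells:
    def test_recovery_of_planted_cells(self, twenty_cell_movie):
        spec, stack, gt = twenty_cell_movie
        result = detect_rtn_cells(stack, mode="full_series")
        accepted = result.accepted
        cls = {c.roi_label: c for c in result.classifications}
        matched: dict[int, int] = {}
        false_pos = 0
        for roi in accepted:
            rr, cc = zip(*roi.pixels)
            overlaps = [m[list(rr), list(cc)].sum() for m in gt.masks]
            best = int(np.argmax(overlaps))
            if overlaps[best] == 0:
                false_pos += 1
            else:
                matched.setdefault(best, roi.label)
        assert len(matched) >= 18  # >= 90% recall
        assert false_pos <= 2
        for idx, label in matched.items():
            err = abs(cls[label].peak_frequency - gt.cells[idx].burst_frequency)
            assert err <= 0.025  # one spectral bin

    def test_out_of_band_cells_all_rejected(self):
        rng = np.random.default_rng(8)
        cells = tuple(
            synthgen.CellSpec(
                center=(10 + 20 * i, 20), radius=2.0, burst_frequency=0.05, burst_amplitude=0.4
            )
            for i in range(3)
        )
        spec = synthgen.MovieSpec(height=72, width=40, n_frames=1800, cells=cells, noise_sd=0.5, seed=8)
        stack, _ = synthgen.generate_calcium_movie(spec)
        result = detect_rtn_cells(stack, mode="full_series")
        assert result.accepted == []

    def test_pure_noise_movie_yields_no_accepted_rois(self):
        spec = synthgen.MovieSpec(height=48, width=48, n_frames=600, noise_sd=1.0, seed=9)
        stack, _ = synthgen.generate_calcium_movie(spec)
        result = detect_rtn_cells(stack, mode="full_series")
        assert len(result.accepted) == 0

    def test_cta_mode_on_synchronized_population(self):
        # a coherent population rhythm: all cells at 0.25 Hz, small jitter
        rng = np.random.default_rng(10)
        cells = tuple(
            synthgen.CellSpec(
                center=(12 + 18 * (i // 3), 12 + 18 * (i % 3)),
                radius=2.0,
                burst_frequency=0.25,
                burst_amplitude=0.5,
                jitter_sd=0.05,
                phase=0.2,
            )
            for i in range(9)
        )
        spec = synthgen.MovieSpec(height=60, width=60, n_frames=1200, cells=cells, noise_sd=0.5, seed=10)
        stack, gt = synthgen.generate_calcium_movie(spec)
        result = detect_rtn_cells(stack, mode="cta")
        assert result.mode == "cta"
        assert len(result.accepted) >= 8

    def test_cta_mode_without_rhythm_advises_fallback(self):
        spec = synthgen.MovieSpec(height=32, width=32, n_frames=400, noise_sd=0.3, seed=11)
        stack, _ = synthgen.generate_calcium_movie(spec)
        with pytest.raises(ValueError, match="full_series"):
            detect_rtn_cells(stack, mode="cta")


class TestFrequencyMeasures:
    def test_burst_frequency_arithmetic(self):
        assert imaging.burst_frequency(list(range(12)), 60.0) == pytest.approx(0.2)
        assert imaging.burst_frequency([], 60.0) == 0.0
        with pytest.raises(ValueError):
            imaging.burst_frequency([1.0], 0.0)

    def test_planted_frequency_step_recovered(self):
        # 1.5x frequency step between two epochs of the same synthetic cell
        fr, dur = 10.0, 180.0
        made = []
        for f in (0.2, 0.3):
            spec = synthgen.MovieSpec(
                height=24,
                width=24,
                n_frames=int(dur * fr),
                cells=(synthgen.CellSpec((12, 12), 2.0, f, 0.5),),
                seed=12,
            )
            _, gt = synthgen.generate_calcium_movie(spec)
            made.append(imaging.burst_frequency(gt.event_times[0], dur))
        assert made[1] / made[0] == pytest.approx(1.5, rel=0.1)

    def test_frequency_comparison_reports_relative_change(self):
        out = imaging.frequency_comparison([0.2, 0.2], [0.3, 0.3])
        assert out["relative_change_pct"] == pytest.approx(50.0)


class TestPhotostimResponseMap:
    def test_step_blob_map(self):
        data = np.zeros((40, 16, 16))
        data[20:, 4:8, 4:8] = 0.1
        dff = imaging.DFFSeries(data=data, w=0, frame_rate=10.0)
        m = photostim_response_map(dff, stim_offset_frame=20, n_frames=10)
        assert m[5, 5] == pytest.approx(0.1)
        assert m[12, 12] == pytest.approx(0.0)

    def test_offset_past_end_rejected(self):
        dff = imaging.DFFSeries(data=np.zeros((15, 4, 4)), w=0, frame_rate=10.0)
        with pytest.raises(ValueError):
            photostim_response_map(dff, stim_offset_frame=10, n_frames=10)

    def test_zero_series_gives_zero_map(self):
        dff = imaging.DFFSeries(data=np.zeros((20, 4, 4)), w=0, frame_rate=10.0)
        assert np.all(photostim_response_map(dff, 5, 10) == 0)
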