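"""Segmentation, tracking, FRET-ratio traces and apoptosis calling."""

import numpy as np
import pandas as pd
import pytest

from resistkit.fret import (
    CellTrace,
    activation_curve,
    classify_apoptosis,
    extract_traces,
    segment_cells,
    traces_from_table,
)
from resistkit.simulate import FretSimConfig, ImageStackPair, simulate_fret_movie


class TestSegmentation:
    def test_count_matches_planted_blobs(self, clean_fret_movie):
        cfg, pair, _, _ = clean_fret_movie
        labels = segment_cells(pair.yfp_stack[0])
        assert labels.max() == cfg.n_cells

    def test_uniform_frame_yields_empty_mask(self):
        assert segment_cells(np.zeros((32, 32))).max() == 0
        assert segment_cells(np.full((32, 32), 7.0)).max() == 0

    def test_intensity_scale_invariance(self, clean_fret_movie):
        """Otsu thresholding is relative: a 10x brighter frame segments
        identically."""
        _, pair, _, _ = clean_fret_movie
        frame = pair.yfp_stack[0]
        assert np.array_equal(segment_cells(frame) > 0, segment_cells(frame * 10) > 0)

    def test_min_area_filter_removes_specks(self):
        frame = np.zeros((40, 40))
        frame[5:15, 5:15] = 10.0  # 100 px cell
        frame[30, 30] = 10.0  # single-pixel speck
        labels = segment_cells(frame, min_area_px=20)
        assert labels.max() == 1

    def test_empty_frame_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            segment_cells(np.empty((0, 0)))


class TestTraceExtraction:
    def test_static_cells_have_stable_tracks(self, clean_fret_movie):
        cfg, pair, _, _ = clean_fret_movie
        traces = extract_traces(pair)
        assert len(traces) == cfg.n_cells
        for tr in traces:
            assert np.isfinite(tr.cfp_mean).all()
            assert len(tr.timepoints) == cfg.n_timepoints

    def test_single_frame_stack_gives_length_one_traces(self):
        cfg = FretSimConfig(n_cells=3, n_timepoints=1, seed=4)
        pair, _, _ = simulate_fret_movie(cfg)
        traces = extract_traces(pair)
        assert len(traces) == 3
        assert all(len(t.timepoints) == 1 for t in traces)

    def test_planted_ratio_drop_recovered_through_imaging_path(self):
        cfg = FretSimConfig(
            n_cells=1, n_timepoints=12, frame_interval=1.0,
            activation_times=[5.0], ratio_drop=0.5, intensity_noise_sd=0.0, seed=2,
        )
        pair, _, _ = simulate_fret_movie(cfg)
        (trace,) = extract_traces(pair)
        pre = trace.fret_ratio[:5].mean()
        post = trace.fret_ratio[5:].mean()
        assert post == pytest.approx(0.5 * pre, rel=1e-3)

    def test_mask_count_mismatch_rejected(self, clean_fret_movie):
        _, pair, _, _ = clean_fret_movie
        with pytest.raises(ValueError, match="one mask per frame"):
            extract_traces(pair, masks=[np.zeros_like(pair.yfp_stack[0], dtype=int)])


class TestApoptosisCall:
    def trace(self, ratios, interval=1.0):
        r = np.asarray(ratios, dtype=float)
        return CellTrace(
            cell_id="c", timepoints=np.arange(len(r)) * interval,
            cfp_mean=np.ones_like(r), yfp_mean=r,
        )

    def test_constant_ratio_not_activated(self):
        activated, t = classify_apoptosis(self.trace([1.0] * 10))
        assert not activated and t is None

    def test_step_drop_called_at_step_frame(self):
        ratios = [1.0] * 5 + [0.5] * 5
        activated, t = classify_apoptosis(self.trace(ratios, interval=2.0))
        assert activated
        assert t == 10.0  # frame 5 at 2 h per frame

    def test_transient_single_frame_dip_ignored(self):
        """A one-frame excursion is not a sustained activation."""
        ratios = [1.0, 1.0, 1.0, 0.4, 1.0, 1.0, 1.0]
        activated, _ = classify_apoptosis(self.trace(ratios))
        assert not activated

    def test_drop_smaller_than_threshold_ignored(self):
        ratios = [1.0] * 4 + [0.8] * 4  # 20% drop < default 30%
        activated, _ = classify_apoptosis(self.trace(ratios))
        assert not activated

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError, match="longer than"):
            classify_apoptosis(self.trace([1.0, 1.0, 0.5]), baseline_frames=3)

    def test_channel_scale_invariance(self):
        """Multiplying both channels by a constant leaves calls unchanged."""
        r = np.array([1.0] * 4 + [0.6] * 4)
        t1 = CellTrace("a", np.arange(8.0), np.ones(8), r)
        t2 = CellTrace("b", np.arange(8.0), np.ones(8) * 37.0, r * 37.0)
        assert np.allclose(t1.fret_ratio, t2.fret_ratio)
        assert classify_apoptosis(t1) == classify_apoptosis(t2)

    def test_noisy_movie_activation_times_within_one_frame(self, noisy_fret_movie):
        cfg, pair, _, truth = noisy_fret_movie
        traces = extract_traces(pair)
        for tr in traces:
            classify_apoptosis(tr)
        est = sorted(t.activation_time for t in traces if t.activated)
        true = sorted(v for v in truth.true_activation.values() if v is not None)
        assert len(est) == len(true)
        errors = [abs(e - t) for e, t in zip(est, true)]
        assert np.median(errors) <= cfg.frame_interval


class TestActivationCurve:
    def make(self, activation_times, n=10):
        traces = []
        for i, at in enumerate(activation_times):
            tr = CellTrace(
                f"c{i}", np.arange(float(n)), np.ones(n), np.ones(n)
            )
            tr.activated = at is not None
            tr.activation_time = at
            traces.append(tr)
        return traces

    def test_no_activation_gives_flat_zero(self):
        curve = activation_curve(self.make([None, None, None]))
        assert (curve["fraction_activated"] == 0).all()

    def test_all_activated_at_time_zero_gives_flat_one(self):
        curve = activation_curve(self.make([0.0, 0.0]))
        assert (curve["fraction_activated"] == 1).all()

    def test_monotone_and_bounded(self, noisy_fret_movie):
        _, pair, _, _ = noisy_fret_movie
        traces = extract_traces(pair)
        for tr in traces:
            classify_apoptosis(tr)
        frac = activation_curve(traces)["fraction_activated"].to_numpy()
        assert (np.diff(frac) >= 0).all()
        assert frac.min() >= 0 and frac.max() <= 1

    def test_matches_empirical_cdf_of_truth(self, clean_fret_movie):
        cfg, pair, _, truth = clean_fret_movie
        traces = extract_traces(pair)
        for tr in traces:
            classify_apoptosis(tr)
        curve = activation_curve(traces)
        true_times = [v for v in truth.true_activation.values() if v is not None]
        for _, row in curve.iterrows():
            # classification fires at the first frame at/after the true switch
            expected = np.mean([t <= row["time_h"] for t in true_times]) * len(
                true_times
            ) / cfg.n_cells
            assert row["fraction_activated"] == pytest.approx(expected, abs=1 / cfg.n_cells)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            activation_curve([])


class TestTraceTableRoundTrip:
    def test_simulator_table_reconstructs_traces(self, clean_fret_movie):
        cfg, _, table, truth = clean_fret_movie
        traces = traces_from_table(table)
        assert len(traces) == cfg.n_cells
        for tr in traces:
            activated, t_est = classify_apoptosis(tr)
            t_true = truth.true_activation[tr.cell_id]
            if t_true is None:
                assert not activated
            else:
                assert activated
                assert 0 <= t_est - t_true <= cfg.frame_interval

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            traces_from_table(pd.DataFrame({"cell_id": ["a"], "time_h": [0.0]}))
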