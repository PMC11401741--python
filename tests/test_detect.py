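"""TIC computation, cell-event detection, merging and cell filtering."""

import numpy as np
import pytest

from scmpipe import (
    DetectionParams,
    SimConfig,
    TicTrace,
    compute_tic,
    consolidate_mz,
    detect_cells,
    filter_cell_matrix,
    filter_occurrences,
    merge_cells,
    score_detection,
    simulate_run,
)
from scmpipe.errors import EmptyMatrixError, InvariantError

from conftest import make_series, nearest_bin


def trace_from_tic(tic, baseline_window=51):
    series = make_series([[(100.0, float(v))] if v > 0 else [] for v in tic])
    return compute_tic(consolidate_mz(series), baseline_window)


class TestComputeTic:
    def test_constant_tic_gives_flat_baseline_and_floor_sigma(self):
        trace = trace_from_tic([100.0] * 30)
        np.testing.assert_allclose(trace.baseline, 100.0)
        assert np.all(trace.sigma == trace.sigma[0])
        assert trace.sigma[0] > 0

    def test_single_spike_does_not_lift_median_baseline(self):
        tic = [10.0] * 40
        tic[20] = 1000.0
        trace = trace_from_tic(tic)
        assert trace.baseline[20] == pytest.approx(10.0)

    def test_baseline_tracks_programmed_background(self, sim1):
        # the rolling-median baseline should sit at the cell-free TIC
        # median (chemical noise is right-skewed, so the mean would not
        # be the right comparator for a median estimator); the estimator's
        # sampling scatter scales as 1/sqrt(window), so the recovery check
        # runs with a window wide enough for ~2-3% scatter and without
        # transients (cell occupancy biases any rolling median upward —
        # conservative for S/N screening, but not "background recovery")
        series, truth = simulate_run(SimConfig(seed=1, n_cells=0))
        trace = compute_tic(series, baseline_window=201)
        ref = truth.tic_background_median
        rel = np.abs(trace.baseline - ref) / ref
        assert (rel < 0.05).mean() >= 0.90

    def test_baseline_bias_from_transients_is_upward_and_bounded(self, sim1):
        # with the default density (50 cells) the rolling median rides up
        # in cell-dense stretches; it must never undershoot the true
        # background by more than the estimator scatter
        series, truth = sim1
        trace = compute_tic(series)
        ref = truth.tic_background_median
        assert np.median(trace.baseline) == pytest.approx(ref, rel=0.10)
        assert (trace.baseline > 0.9 * ref).all()

    def test_window_must_be_odd(self):
        with pytest.raises(InvariantError, match="odd"):
            DetectionParams(baseline_window=50)


class TestDetectCells:
    def test_flat_trace_yields_no_events(self):
        assert detect_cells(trace_from_tic([50.0] * 60)) == []

    def test_single_gaussian_transient_detected_once(self):
        x = np.arange(200)
        tic = 100.0 + 5000.0 * np.exp(-0.5 * ((x - 100) / 2.0) ** 2)
        rng = np.random.default_rng(0)
        tic += rng.normal(0, 5, x.size)
        events = detect_cells(trace_from_tic(np.maximum(tic, 1.0)))
        assert len(events) == 1
        assert events[0].start <= 100 < events[0].end
        assert events[0].apex_snr >= 3.0

    def test_recall_and_precision_on_synthetic_run(self, sim1, events1):
        _, truth = sim1
        recall, precision, _ = score_detection(events1, truth)
        assert recall >= 0.95
        assert precision >= 0.95

    def test_detection_invariant_under_intensity_scaling(self, sim1):
        series, _ = sim1
        table = filter_occurrences(consolidate_mz(series), 10)
        trace = compute_tic(table)
        scaled = TicTrace(
            trace.scan_index,
            trace.retention_time,
            trace.tic * 1000.0,
            trace.baseline * 1000.0,
            trace.sigma * 1000.0,
        )
        a = [(e.start, e.end, e.apex_scan) for e in detect_cells(trace)]
        b = [(e.start, e.end, e.apex_scan) for e in detect_cells(scaled)]
        assert a == b

    def test_spans_pairwise_disjoint_and_snr_holds(self, events1):
        spans = sorted((e.start, e.end) for e in events1)
        for (s0, e0), (s1, _) in zip(spans, spans[1:]):
            assert e0 <= s1
        assert all(e.apex_snr >= 3.0 for e in events1)

    def test_recall_degrades_as_amplitude_shrinks(self):
        recalls = []
        for scale in (1.0, 0.02, 0.004):
            cfg = SimConfig(seed=6, n_scans=1200, n_cells=15)
            cfg.cell_types = [
                (label, [(mz, amp * scale, sig) for mz, amp, sig in panel])
                for label, panel in cfg.cell_types
            ]
            series, truth = simulate_run(cfg)
            table = filter_occurrences(consolidate_mz(series), 10)
            events = detect_cells(compute_tic(table))
            recalls.append(score_detection(events, truth)[0])
        assert recalls[0] >= recalls[1] >= recalls[2]
        assert recalls[0] > recalls[2]


class TestMergeCells:
    def test_span_sum(self):
        from scmpipe.model import CellEvent

        scans = [[] for _ in range(14)]
        scans[10] = [(100.0, 5.0)]
        scans[11] = [(100.0, 7.0)]
        table = consolidate_mz(make_series(scans))
        ev = CellEvent(0, 10, 10, 12, 5.0, noise_scans=[7, 8])
        m = merge_cells(table, [ev])
        assert m.values[0, 0] == pytest.approx(12.0)
        assert m.layer == "raw"
        assert m.cell_meta.loc[0, "apex_rt_s"] == pytest.approx(10.0)

    def test_bin_absent_in_span_gives_zero(self):
        from scmpipe.model import CellEvent

        scans = [[] for _ in range(14)]
        scans[2] = [(100.0, 5.0)]
        scans[10] = [(200.0, 7.0)]
        table = consolidate_mz(make_series(scans))
        m = merge_cells(table, [CellEvent(0, 10, 10, 11, 5.0)])
        assert m.values[0, 0] == 0.0  # bin at 100 Th never occurs in the span
        assert m.values[0, 1] == pytest.approx(7.0)

    def test_span_outside_table_rejected(self):
        from scmpipe.model import CellEvent

        table = consolidate_mz(make_series([[(100.0, 1.0)]] * 5))
        with pytest.raises(InvariantError, match="outside"):
            merge_cells(table, [CellEvent(0, 7, 7, 9, 5.0)])

    def test_marker_recovery_before_denoising(self, sim1, table1, events1, matched1):
        _, truth = sim1
        m = merge_cells(table1, events1)
        bins_mz = m.feature_mz
        errs = []
        for i, cid in enumerate(m.cell_ids):
            if cid not in matched1:
                continue
            for met_mz, true_val in truth.cell_intensities[matched1[cid]].items():
                col = nearest_bin(bins_mz, met_mz)
                if col is not None:
                    errs.append(abs(m.values[i, col] - true_val) / true_val)
        assert np.median(errs) <= 0.15


class TestFilterCellMatrix:
    @staticmethod
    def _matrix(nonzero_per_cell):
        import pandas as pd

        from scmpipe.model import CellMatrix

        n_feat = 12
        rows = []
        for k in nonzero_per_cell:
            row = np.zeros(n_feat)
            row[:k] = 1.0
            rows.append(row)
        meta = pd.DataFrame({"cell_id": range(len(rows)), "batch": "b0"})
        return CellMatrix(
            np.array(rows), np.arange(n_feat) + 100.0, list(range(len(rows))), meta
        )

    def test_cell_below_min_features_removed(self):
        out = filter_cell_matrix(self._matrix([9, 11]), 10)
        assert out.cell_ids == [1]

    def test_min_features_zero_is_identity(self):
        out = filter_cell_matrix(self._matrix([0, 3, 12]), 0)
        assert out.n_cells == 3

    def test_all_cells_removed_raises_with_advice(self):
        with pytest.raises(EmptyMatrixError, match="min_features"):
            filter_cell_matrix(self._matrix([1, 2]), 10)

    def test_debris_events_removed_after_denoising(self):
        from scmpipe import estimate_noise, screen_and_subtract

        series, truth = simulate_run(
            SimConfig(seed=9, n_scans=2000, n_cells=20, n_debris=3)
        )
        table = filter_occurrences(consolidate_mz(series), 10)
        events = detect_cells(compute_tic(table))
        m = merge_cells(table, events)
        den = screen_and_subtract(m, [estimate_noise(table, e) for e in events])
        kept = filter_cell_matrix(den, 10)
        _, _, pairs = score_detection(events, truth)
        debris_truth = set(truth.cells[truth.cells.is_debris].truth_id)
        debris_dets = {d for d, t in pairs if t in debris_truth}
        real_dets = {d for d, t in pairs if t not in debris_truth}
        assert debris_dets and debris_dets.isdisjoint(kept.cell_ids)
        assert real_dets <= set(kept.cell_ids)
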