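"""Time trimming, offset correction, m/z consolidation, occurrence filter."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scmpipe import (
    OffsetModel,
    SimConfig,
    apply_offset,
    consolidate_mz,
    cut,
    estimate_offset,
    filter_occurrences,
    simulate_run,
)
from scmpipe.errors import EmptyRunError, InvariantError, LowCoverageError

from conftest import make_series


def brute_force_single_linkage(mz_values, resolution):
    """Independent O(n^2) oracle: transitively merge all pairs within
    resolution, returning the partition as sorted tuples of indices."""
    n = len(mz_values)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if abs(mz_values[i] - mz_values[j]) <= resolution:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
    clusters = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)
    return sorted(tuple(sorted(c)) for c in clusters.values())


def _partition_from_table(series, table):
    """Recover the implementation's partition of the pooled m/z values."""
    all_mz = np.concatenate([s.mz for s in series.spectra])
    order = np.argsort(all_mz, kind="stable")
    rep = table.bins["representative_mz"].to_numpy()
    # assign each raw value to its nearest representative, then group
    edges = (rep[1:] + rep[:-1]) / 2
    assign = np.searchsorted(edges, all_mz[order])
    groups = {}
    for raw_idx, b in zip(order, assign):
        groups.setdefault(int(b), []).append(int(raw_idx))
    return sorted(tuple(sorted(g)) for g in groups.values())


class TestCut:
    def test_full_range_is_identity(self):
        series = make_series([[(100.0, 1.0)]] * 4)
        out = cut(series, 0.0, 100.0)
        assert out.n_scans == 4

    def test_half_open_window(self):
        series = make_series([[(100.0, 1.0)]] * 4)  # times 0,1,2,3
        out = cut(series, 1.0, 3.0)
        assert [s.retention_time for s in out.spectra] == [1.0, 2.0]
        assert [s.scan_index for s in out.spectra] == [1, 2]  # not renumbered

    def test_empty_window_names_bounds(self):
        series = make_series([[(100.0, 1.0)]] * 4)
        with pytest.raises(EmptyRunError, match="10.*20"):
            cut(series, 10.0, 20.0)

    def test_cutting_away_all_cells_leaves_none_to_detect(self):
        from scmpipe import DetectionParams, compute_tic, detect_cells

        series, _ = simulate_run(SimConfig(seed=1, n_scans=1500, n_cells=10))
        head = cut(series, 0.0, 100.0)  # cells are programmed in [100, 500] s
        table = filter_occurrences(consolidate_mz(head), 10)
        events = detect_cells(compute_tic(table), DetectionParams())
        assert events == []


class TestOffset:
    @staticmethod
    def _lockmass_series(delta=0.0, n=40, ref=445.12):
        return make_series([[(ref + delta, 50.0)] for _ in range(n)])

    def test_peaks_exactly_at_reference_give_zero_delta(self):
        model = estimate_offset(self._lockmass_series(), 445.12, tol=0.02)
        assert model.delta_mz == pytest.approx(0.0, abs=1e-12)

    def test_injected_shift_recovered_on_synthetic_run(self):
        series, _ = simulate_run(SimConfig(seed=2, drift_delta=0.005))
        model = estimate_offset(series, 445.1200, tol=0.02)
        assert model.delta_mz == pytest.approx(0.005, abs=1e-4)
        corrected = apply_offset(series, model)
        residual = estimate_offset(corrected, 445.1200, tol=0.02)
        assert abs(residual.delta_mz) < 1e-4

    def test_absent_reference_is_low_coverage(self):
        series = make_series([[(100.0, 1.0)]] * 10)
        with pytest.raises(LowCoverageError, match="50%"):
            estimate_offset(series, 445.12, tol=0.02)

    def test_zero_delta_is_identity(self):
        series = self._lockmass_series(delta=0.003)
        out = apply_offset(series, OffsetModel(delta_mz=0.0))
        np.testing.assert_array_equal(out.spectra[0].mz, series.spectra[0].mz)

    def test_applying_twice_equals_double_delta(self):
        series = self._lockmass_series()
        twice = apply_offset(apply_offset(series, OffsetModel(0.004)), OffsetModel(0.004))
        once = apply_offset(series, OffsetModel(0.008))
        np.testing.assert_allclose(twice.spectra[0].mz, once.spectra[0].mz)

    def test_sanity_bound_on_delta(self):
        with pytest.raises(InvariantError, match="sanity"):
            OffsetModel(delta_mz=1.5)


class TestConsolidate:
    def test_gap_below_resolution_merges(self):
        series = make_series([[(150.0000, 10.0)], [(150.0049, 20.0)]])
        table = consolidate_mz(series, 0.01)
        assert table.n_bins == 1
        # intensity-weighted representative
        assert table.bins.representative_mz.iloc[0] == pytest.approx(
            (150.0 * 10 + 150.0049 * 20) / 30
        )

    def test_gap_above_resolution_splits(self):
        series = make_series([[(150.000, 10.0)], [(150.020, 20.0)]])
        assert consolidate_mz(series, 0.01).n_bins == 2

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        mz = rng.uniform(100, 110, 200)
        series = make_series([[(m, 1.0 + i) for i, m in enumerate(np.sort(mz))]])
        table = consolidate_mz(series, 0.01)
        assert _partition_from_table(series, table) == brute_force_single_linkage(
            np.sort(mz), 0.01
        )

    def test_total_intensity_conserved(self, sim1, table1):
        series, _ = sim1
        raw_total = series.total_intensity()
        table = consolidate_mz(series, 0.01)
        assert table.total_intensity() == pytest.approx(raw_total, rel=1e-12)

    def test_scan_order_independence(self):
        rng = np.random.default_rng(5)
        scans = [
            [(float(m), float(v)) for m, v in zip(np.sort(rng.uniform(100, 105, 10)),
                                                  rng.exponential(10, 10))]
            for _ in range(6)
        ]
        fwd = consolidate_mz(make_series(scans), 0.01)
        rev = consolidate_mz(make_series(scans[::-1]), 0.01)
        np.testing.assert_allclose(
            fwd.bins.representative_mz, rev.bins.representative_mz
        )
        assert list(fwd.bins.occurrence) == list(rev.bins.occurrence)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_raising_resolution_never_increases_bin_count(self, seed):
        rng = np.random.default_rng(seed)
        mz = np.sort(rng.uniform(100, 101, 50))
        series = make_series([[(float(m), 1.0) for m in mz]])
        counts = [consolidate_mz(series, r).n_bins for r in (0.001, 0.01, 0.1)]
        assert counts[0] >= counts[1] >= counts[2]

    def test_nonpositive_resolution_rejected(self):
        with pytest.raises(InvariantError):
            consolidate_mz(make_series([[(100.0, 1.0)]]), 0.0)


class TestFilterOccurrences:
    @staticmethod
    def _table(n_scans_present):
        scans = [
            [(100.0, 1.0)] if i < n_scans_present else []
            for i in range(12)
        ]
        return consolidate_mz(make_series(scans), 0.01)

    def test_bin_in_nine_scans_removed_at_default(self):
        assert filter_occurrences(self._table(9), 10).n_bins == 0

    def test_bin_in_ten_scans_retained_strict_less_semantics(self):
        assert filter_occurrences(self._table(10), 10).n_bins == 1

    def test_min_occurrence_one_is_identity(self, table1):
        out = filter_occurrences(table1, 1)
        assert out.n_bins == table1.n_bins

    def test_bin_ids_recompacted_and_occurrence_consistent(self, table1):
        out = filter_occurrences(table1, 10)
        assert list(out.bins.index) == list(range(out.n_bins))
        np.testing.assert_array_equal(
            out.recount_occurrence().to_numpy(), out.bins.occurrence.to_numpy()
        )

    def test_monotone_in_threshold(self, sim1):
        series, _ = sim1
        table = consolidate_mz(series, 0.01)
        counts = [filter_occurrences(table, k).n_bins for k in (1, 5, 10, 50)]
        assert sorted(counts, reverse=True) == counts
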