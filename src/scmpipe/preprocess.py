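"""Scan-series preprocessing: time trimming, m/z drift correction,
adjacent-peak consolidation and occurrence filtering.

Consolidation is gap-based single-linkage clustering of the run's pooled
m/z values: a new bin starts whenever the gap to the previous sorted m/z
exceeds the resolution (default 0.01 Th, matching the reliable resolution
of Orbitrap-class instruments). This merges the scan-to-scan scatter of a
real peak without the edge-splitting artefacts of a fixed grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EmptyRunError, InvariantError, LowCoverageError
from .model import PeakTable, ScanSeries, Spectrum

logger = logging.getLogger(__name__)


@dataclass
class OffsetModel:
    """A constant additive m/z shift, optionally with per-scan diagnostics."""

    delta_mz: float
    source: str = "user_supplied"  # or "lockmass_estimated"
    reference_mz: float | None = None
    per_scan: list[float] | None = None
    max_abs_delta: float = 1.0  # sanity bound, Th

    def __post_init__(self) -> None:
        if abs(self.delta_mz) >= self.max_abs_delta:
            raise InvariantError(
                f"|delta_mz| = {abs(self.delta_mz):.4g} exceeds the sanity "
                f"bound of {self.max_abs_delta} Th"
            )


def cut(series: ScanSeries, t_start: float, t_end: float) -> ScanSeries:
    """Keep scans with ``t_start <= retention_time < t_end``.

    Scan indices are preserved (not renumbered) so downstream objects can
    still be related to the raw series.
    """
    if t_start >= t_end:
        raise InvariantError(f"cut window [{t_start}, {t_end}) is empty")
    kept = [s for s in series.spectra if t_start <= s.retention_time < t_end]
    if not kept:
        raise EmptyRunError(
            f"no scans in the window [{t_start} s, {t_end} s)"
        )
    return ScanSeries(
        [Spectrum(s.scan_index, s.retention_time, s.mz.copy(), s.intensity.copy()) for s in kept],
        source_files=list(series.source_files),
        polarity=series.polarity,
        meta=dict(series.meta),
    )


def estimate_offset(
    series: ScanSeries, reference_mz: float, tol: float = 0.02
) -> OffsetModel:
    """Estimate a constant m/z shift from a lock-mass reference ion.

    For every scan, the observed peak nearest to ``reference_mz`` within
    ``±tol`` contributes one delta; the model delta is the median over
    scans. Scans without a peak in the window are skipped; if fewer than
    half the scans cover the reference the estimate is refused.
    """
    deltas: list[float] = []
    for s in series.spectra:
        if s.mz.size == 0:
            continue
        lo = np.searchsorted(s.mz, reference_mz - tol, side="left")
        hi = np.searchsorted(s.mz, reference_mz + tol, side="right")
        if hi <= lo:
            continue
        window = s.mz[lo:hi]
        nearest = window[np.argmin(np.abs(window - reference_mz))]
        deltas.append(float(nearest - reference_mz))
    coverage = len(deltas) / max(series.n_scans, 1)
    if coverage < 0.5:
        raise LowCoverageError(
            f"lock mass {reference_mz} found in {coverage:.0%} of scans "
            "(need >= 50%)"
        )
    return OffsetModel(
        delta_mz=float(np.median(deltas)),
        source="lockmass_estimated",
        reference_mz=reference_mz,
        per_scan=deltas,
    )


def apply_offset(series: ScanSeries, model: OffsetModel) -> ScanSeries:
    """Shift every m/z by ``-delta_mz``; intensities untouched."""
    return ScanSeries(
        [
            Spectrum(s.scan_index, s.retention_time, s.mz - model.delta_mz, s.intensity.copy())
            for s in series.spectra
        ],
        source_files=list(series.source_files),
        polarity=series.polarity,
        meta=dict(series.meta),
    )


def consolidate_mz(series: ScanSeries, resolution: float = 0.01) -> PeakTable:
    """Merge adjacent m/z values across the whole run into feature bins.

    Single-linkage over the pooled, sorted m/z multiset: a gap larger
    than ``resolution`` starts a new bin. Representative m/z is the
    intensity-weighted mean of bin members; per-(scan, bin) intensities
    are summed, so total ion intensity is conserved exactly.
    """
    if resolution <= 0:
        raise InvariantError("resolution must be > 0")
    scan_rt = pd.Series(
        series.retention_times, index=pd.Index(series.scan_indices, name="scan_index")
    )
    parts_scan = [np.full(s.mz.size, s.scan_index, dtype=np.int64) for s in series.spectra]
    if not parts_scan or sum(p.size for p in parts_scan) == 0:
        bins = pd.DataFrame(
            columns=["representative_mz", "member_count", "occurrence"]
        ).rename_axis("bin_id")
        rows = pd.DataFrame(columns=["scan_index", "bin_id", "intensity"])
        return PeakTable(rows, bins, scan_rt)
    all_scan = np.concatenate(parts_scan)
    all_mz = np.concatenate([s.mz for s in series.spectra])
    all_int = np.concatenate([s.intensity for s in series.spectra])

    order = np.argsort(all_mz, kind="stable")
    mz_s, int_s, scan_s = all_mz[order], all_int[order], all_scan[order]
    gaps = np.diff(mz_s)
    bin_of = np.concatenate([[0], np.cumsum(gaps > resolution)]).astype(np.int64)
    n_bins = int(bin_of[-1]) + 1

    w_sum = np.bincount(bin_of, weights=int_s, minlength=n_bins)
    wmz_sum = np.bincount(bin_of, weights=int_s * mz_s, minlength=n_bins)
    member_count = np.bincount(bin_of, minlength=n_bins)
    # intensity-weighted mean; plain mean if a bin is all-zero intensity
    rep = np.where(
        w_sum > 0,
        wmz_sum / np.where(w_sum > 0, w_sum, 1.0),
        np.bincount(bin_of, weights=mz_s, minlength=n_bins) / np.maximum(member_count, 1),
    )

    rows = (
        pd.DataFrame({"scan_index": scan_s, "bin_id": bin_of, "intensity": int_s})
        .groupby(["scan_index", "bin_id"], as_index=False)["intensity"]
        .sum()
    )
    pos = rows[rows["intensity"] > 0]
    occ = (
        pos.groupby("bin_id")["scan_index"]
        .nunique()
        .reindex(range(n_bins), fill_value=0)
        .to_numpy()
    )
    bins = pd.DataFrame(
        {
            "representative_mz": rep,
            "member_count": member_count.astype(np.int64),
            "occurrence": occ.astype(np.int64),
        },
        index=pd.RangeIndex(n_bins, name="bin_id"),
    )
    return PeakTable(rows, bins, scan_rt)


def filter_occurrences(table: PeakTable, min_occurrence: int = 10) -> PeakTable:
    """Drop bins seen (with positive intensity) in fewer than
    ``min_occurrence`` distinct scans; surviving bin ids are re-compacted.
    """
    if min_occurrence < 1:
        raise InvariantError("min_occurrence must be >= 1")
    keep = table.bins[table.bins["occurrence"] >= min_occurrence]
    removed = len(table.bins) - len(keep)
    logger.info(
        "occurrence filter (>= %d scans): kept %d of %d bins",
        min_occurrence, len(keep), len(table.bins),
    )
    remap = pd.Series(
        np.arange(len(keep), dtype=np.int64), index=keep.index
    )
    rows = table.rows[table.rows["bin_id"].isin(set(keep.index))].copy()
    rows["bin_id"] = rows["bin_id"].map(remap).astype(np.int64)
    bins = keep.reset_index(drop=True).rename_axis("bin_id")
    out = PeakTable(rows, bins, table.scan_rt.copy())
    logger.debug("occurrence filter removed %d bins", removed)
    return out
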