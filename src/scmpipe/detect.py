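"""Cell-event detection on the total ion current (TIC).

A cell passing through the ion source produces a transient a few scans
wide on top of a slowly varying background. Detection is classic robust
peak picking: rolling-median baseline, rolling-MAD noise scale, local
maxima of the (median-smoothed) TIC screened at a signal-to-noise
threshold of 3, valley-bounded spans, and flanking noise windows that
later feed the per-cell noise model. S/N is scale-free, so detection is
invariant under uniform intensity scaling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .errors import EmptyMatrixError, InvariantError
from .model import CellEvent, CellMatrix, PeakTable, ScanSeries

logger = logging.getLogger(__name__)


@dataclass
class TicTrace:
    """Per-scan TIC with its rolling baseline and robust noise scale."""

    scan_index: np.ndarray
    retention_time: np.ndarray
    tic: np.ndarray
    baseline: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        n = self.scan_index.size
        if not (
            self.retention_time.size == n
            and self.tic.size == n
            and self.baseline.size == n
            and self.sigma.size == n
        ):
            raise InvariantError("TicTrace arrays must have equal length")
        if self.sigma.size and self.sigma.min() < 0:
            raise InvariantError("sigma must be >= 0")


@dataclass
class DetectionParams:
    """Tunables of the TIC peak picker.

    ``snr_threshold`` is the one value fixed by the method (3x S/N); the
    window sizes are implementation parameters in scans.
    """

    snr_threshold: float = 3.0
    baseline_window: int = 51
    smooth_window: int = 3
    max_halfwidth: int = 10
    min_separation: int = 2
    noise_margin: int = 5

    def __post_init__(self) -> None:
        if self.snr_threshold <= 0:
            raise InvariantError("snr_threshold must be > 0")
        for name in ("baseline_window", "smooth_window"):
            w = getattr(self, name)
            if w < 1 or w % 2 == 0:
                raise InvariantError(f"{name} must be odd and >= 1, got {w}")
        if self.max_halfwidth < 1 or self.min_separation < 1 or self.noise_margin < 0:
            raise InvariantError("window parameters out of range")


def _rolling_median(x: np.ndarray, window: int) -> np.ndarray:
    return (
        pd.Series(x)
        .rolling(window, center=True, min_periods=1)
        .median()
        .to_numpy()
    )


def compute_tic(
    source: PeakTable | ScanSeries, baseline_window: int = 51
) -> TicTrace:
    """Sum intensities per scan and estimate baseline and noise scale.

    Baseline is an edge-truncated centred rolling median; sigma is
    1.4826 x the rolling median absolute deviation about the baseline,
    floored at the smallest positive deviation so it is never zero.
    """
    if isinstance(source, PeakTable):
        scan_idx = source.scan_rt.index.to_numpy(dtype=np.int64)
        rts = source.scan_rt.to_numpy(dtype=float)
        sums = source.rows.groupby("scan_index")["intensity"].sum()
        tic = sums.reindex(source.scan_rt.index, fill_value=0.0).to_numpy(dtype=float)
    else:
        scan_idx = source.scan_indices
        rts = source.retention_times
        tic = np.array([s.intensity.sum() for s in source.spectra], dtype=float)
    if scan_idx.size == 0:
        raise InvariantError("cannot compute TIC of an empty run")
    baseline = _rolling_median(tic, baseline_window)
    dev = np.abs(tic - baseline)
    positive = dev[dev > 0]
    floor = float(positive.min()) if positive.size else 1.0
    sigma = np.maximum(1.4826 * _rolling_median(dev, baseline_window), floor)
    return TicTrace(scan_idx, rts, tic, baseline, sigma)


def detect_cells(trace: TicTrace, params: DetectionParams | None = None) -> list[CellEvent]:
    """Pick cell transients from a TIC trace.

    Candidate apexes are local maxima of the median-smoothed TIC whose
    S/N ``(tic - baseline)/sigma`` meets the threshold on both the raw
    and the smoothed trace (the persistence requirement that rejects
    single-scan spikes a real multi-scan transient always survives).
    Spans grow
    from the apex until the TIC falls back into the noise band
    (``baseline + sigma``) or rises again past a valley, capped at
    ``max_halfwidth`` scans per side. Apexes closer than
    ``min_separation`` keep only the higher; overlapping spans are split
    at the valley between apexes. Noise scans are the ``noise_margin``
    scans flanking each span, minus any scan inside another event's span.
    """
    p = params or DetectionParams()
    n = trace.tic.size
    smoothed = _rolling_median(trace.tic, p.smooth_window)
    snr = (trace.tic - trace.baseline) / trace.sigma

    snr_smoothed = (smoothed - trace.baseline) / trace.sigma

    peaks, _ = find_peaks(smoothed, plateau_size=(1, None))
    accepted = [
        i
        for i in peaks
        if snr[i] >= p.snr_threshold and snr_smoothed[i] >= p.snr_threshold
    ]
    # median smoothing flattens a symmetric apex into a plateau whose edge
    # find_peaks reports; snap each accepted candidate to the raw-TIC
    # maximum within the smoothing half-window (screening happens first so
    # single-scan spikes rejected by the smoothing stay rejected)
    half = p.smooth_window // 2
    refined = {
        int(lo + np.argmax(trace.tic[lo : i + half + 1]))
        for i in accepted
        for lo in (max(0, i - half),)
    }
    cands = [i for i in sorted(refined) if snr[i] >= p.snr_threshold]
    # enforce min_separation, keeping the higher apex
    cands.sort(key=lambda i: (-trace.tic[i], i))
    kept: list[int] = []
    for i in cands:
        if all(abs(i - j) >= p.min_separation for j in kept):
            kept.append(i)
    kept.sort()

    spans: list[tuple[int, int, int]] = []  # (start, end, apex) as positions
    noise_band = trace.baseline + trace.sigma
    for apex in kept:
        start = apex
        while (
            start - 1 >= 0
            and apex - (start - 1) <= p.max_halfwidth
            and trace.tic[start - 1] > noise_band[start - 1]
            and trace.tic[start - 1] <= trace.tic[start]
        ):
            start -= 1
        end = apex + 1
        while (
            end < n
            and end - apex <= p.max_halfwidth
            and trace.tic[end] > noise_band[end]
            and trace.tic[end] <= trace.tic[end - 1]
        ):
            end += 1
        spans.append((start, end, apex))

    # split overlaps at the valley between the two apexes
    for k in range(len(spans) - 1):
        s0, e0, a0 = spans[k]
        s1, e1, a1 = spans[k + 1]
        if e0 > s1:
            valley = a0 + 1 + int(np.argmin(trace.tic[a0 + 1 : a1 + 1]))
            valley = max(a0 + 1, min(valley, a1))
            spans[k] = (s0, valley, a0)
            spans[k + 1] = (valley, e1, a1)

    in_span = np.zeros(n, dtype=bool)
    for s, e, _ in spans:
        in_span[s:e] = True

    events: list[CellEvent] = []
    for cid, (s, e, a) in enumerate(spans):
        lo = max(0, s - p.noise_margin)
        hi = min(n, e + p.noise_margin)
        noise_pos = [i for i in range(lo, s) if not in_span[i]]
        noise_pos += [i for i in range(e, hi) if not in_span[i]]
        events.append(
            CellEvent(
                cell_id=cid,
                apex_scan=int(trace.scan_index[a]),
                start=int(trace.scan_index[s]),
                end=int(trace.scan_index[e - 1]) + 1,
                apex_snr=float(snr[a]),
                noise_scans=[int(trace.scan_index[i]) for i in noise_pos],
            )
        )
    logger.info("detected %d cell events (snr >= %g)", len(events), p.snr_threshold)
    return events


def merge_cells(table: PeakTable, events: list[CellEvent]) -> CellMatrix:
    """Sum each bin's intensity over every event's scan span.

    Produces the raw-layer cells x features matrix; features are all
    surviving bins, in m/z order.
    """
    lo, hi = table.scan_range
    for ev in events:
        if ev.start < lo or ev.end > hi + 1:
            raise InvariantError(
                f"cell {ev.cell_id} span [{ev.start}, {ev.end}) outside "
                f"table scan range [{lo}, {hi}]"
            )
    n_bins = table.n_bins
    values = np.zeros((len(events), n_bins), dtype=float)
    scan_arr = table.rows["scan_index"].to_numpy()
    bin_arr = table.rows["bin_id"].to_numpy()
    int_arr = table.rows["intensity"].to_numpy(dtype=float)
    owner = {}
    for ci, ev in enumerate(events):
        for s in ev.span_scans():
            owner[s] = ci
    owner_of_row = np.array([owner.get(s, -1) for s in scan_arr], dtype=np.int64)
    mask = owner_of_row >= 0
    np.add.at(values, (owner_of_row[mask], bin_arr[mask]), int_arr[mask])

    meta = pd.DataFrame(
        {
            "cell_id": [ev.cell_id for ev in events],
            "apex_scan": [ev.apex_scan for ev in events],
            "apex_rt_s": [float(table.scan_rt.get(ev.apex_scan, np.nan)) for ev in events],
            "apex_snr": [ev.apex_snr for ev in events],
            "start": [ev.start for ev in events],
            "end": [ev.end for ev in events],
            "batch": "batch0",
            "group": "",
        }
    )
    return CellMatrix(
        values,
        table.bins["representative_mz"].to_numpy(),
        [ev.cell_id for ev in events],
        meta,
        layer="raw",
    )


def filter_cell_matrix(matrix: CellMatrix, min_features: int = 10) -> CellMatrix:
    """Drop cells with fewer than ``min_features`` nonzero features."""
    matrix.require_layer("raw", "denoised")
    nz = (matrix.values > 0).sum(axis=1)
    keep = nz >= min_features
    if not keep.any():
        raise EmptyMatrixError(
            "cell-matrix filter removed every cell; review min_features "
            f"(={min_features}) and upstream detection parameters"
        )
    removed = [cid for cid, k in zip(matrix.cell_ids, keep) if not k]
    if removed:
        logger.info("cell-matrix filter removed %d cells: %s", len(removed), removed)
    out = CellMatrix(
        matrix.values[keep],
        matrix.feature_mz,
        [cid for cid, k in zip(matrix.cell_ids, keep) if k],
        matrix.cell_meta.loc[keep].reset_index(drop=True),
        layer=matrix.layer,
        provenance=list(matrix.provenance),
        log_base=matrix.log_base,
    )
    out.provenance.append({"op": "filter_cell_matrix", "min_features": min_features, "removed": removed})
    return out
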