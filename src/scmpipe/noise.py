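"""Per-cell local noise estimation and subtraction.

Rather than subtracting one run-wide background, the noise for every cell
is estimated from the scans immediately flanking that cell's transient
(excluding any scan inside another cell's span). Each feature is then
screened at 3x S/N against its local per-scan noise level and, if valid,
the noise integrated over the event span is subtracted. This keeps a
feature whose signal is genuine at one point of the run even if the
background drifts elsewhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import InvariantError
from .model import CellEvent, CellMatrix, PeakTable

logger = logging.getLogger(__name__)


@dataclass
class NoiseProfile:
    """Per-bin background level (intensity/scan) local to one cell."""

    cell_id: int
    levels: np.ndarray  # one per bin, aligned with PeakTable bin ids
    n_noise_scans: int
    global_floor: float

    def __post_init__(self) -> None:
        if self.n_noise_scans < 1:
            raise InvariantError("n_noise_scans must be >= 1")
        if self.levels.size and self.levels.min() < 0:
            raise InvariantError("noise levels must be >= 0")
        if self.global_floor < 0:
            raise InvariantError("global_floor must be >= 0")


def _per_bin_median(table: PeakTable, scans: list[int]) -> np.ndarray:
    """Median intensity per bin over the given scans, absent = 0."""
    n_bins = table.n_bins
    n_scans = len(scans)
    rows = table.rows[table.rows["scan_index"].isin(set(scans))]
    grid = np.zeros((n_scans, n_bins), dtype=float)
    pos = {s: i for i, s in enumerate(scans)}
    if len(rows):
        r = np.array([pos[s] for s in rows["scan_index"]], dtype=np.int64)
        c = rows["bin_id"].to_numpy(dtype=np.int64)
        grid[r, c] = rows["intensity"].to_numpy(dtype=float)
    return np.median(grid, axis=0)


def estimate_noise(table: PeakTable, event: CellEvent) -> NoiseProfile:
    """Estimate the background around one cell.

    Per-bin noise is the median intensity of the bin over the event's
    flanking noise scans (scans where the bin is absent count as zero).
    ``global_floor`` — the median of the positive per-bin levels — serves
    as the fallback noise scale for bins with an empty local estimate, so
    the S/N screen never divides by zero.
    """
    scans = list(event.noise_scans)
    if not scans:
        logger.warning(
            "cell %d has no noise scans; falling back to run-wide medians",
            event.cell_id,
        )
        scans = [int(s) for s in table.scan_rt.index]
    levels = _per_bin_median(table, scans)
    positive = levels[levels > 0]
    floor = float(np.median(positive)) if positive.size else 0.0
    return NoiseProfile(
        cell_id=event.cell_id,
        levels=levels,
        n_noise_scans=len(scans),
        global_floor=floor,
    )


def screen_and_subtract(
    matrix: CellMatrix,
    profiles: list[NoiseProfile],
    snr_threshold: float = 3.0,
) -> CellMatrix:
    """Screen each (cell, feature) at S/N and subtract local noise.

    With span length ``L`` scans (from the matrix's per-cell metadata),
    the per-scan mean event intensity ``m = value / L`` is compared
    against ``snr_threshold x max(noise, global_floor)``; valid entries
    become ``max(0, value - L x noise)``, invalid entries become 0. The
    output is the denoised layer.
    """
    matrix.require_layer("raw")
    if len(profiles) != matrix.n_cells:
        raise InvariantError("need exactly one noise profile per cell")
    by_id = {p.cell_id: p for p in profiles}
    if set(by_id) != set(matrix.cell_ids):
        raise InvariantError("profile cell ids do not match the matrix")
    span_len = (
        matrix.cell_meta["end"].to_numpy() - matrix.cell_meta["start"].to_numpy()
    )

    out = np.zeros_like(matrix.values)
    for i, cid in enumerate(matrix.cell_ids):
        prof = by_id[cid]
        if prof.levels.size != matrix.n_features:
            raise InvariantError(
                f"profile for cell {cid} covers {prof.levels.size} bins, "
                f"matrix has {matrix.n_features}"
            )
        L = int(span_len[i])
        value = matrix.values[i]
        mean_intensity = value / L
        scale = np.maximum(prof.levels, prof.global_floor)
        valid = mean_intensity >= snr_threshold * scale
        out[i] = np.where(valid, np.maximum(0.0, value - L * prof.levels), 0.0)

    result = CellMatrix(
        out,
        matrix.feature_mz,
        list(matrix.cell_ids),
        matrix.cell_meta.copy(),
        layer="denoised",
        provenance=list(matrix.provenance),
        log_base=matrix.log_base,
    )
    result.provenance.append(
        {"op": "screen_and_subtract", "snr_threshold": snr_threshold}
    )
    return result
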