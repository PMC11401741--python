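"""Shared data model for time-series single-cell metabolomics runs.

The layers mirror the stages of the processing pipeline:

* :class:`ScanSeries` — the raw layer: an ordered list of centroided MS1
  :class:`Spectrum` objects with run metadata.
* :class:`PeakTable` — long-format (scan, bin, intensity) rows after m/z
  consolidation, plus per-bin summary statistics.
* :class:`CellEvent` — one detected cell transient in the TIC, with the
  flanking scans used for local noise estimation.
* :class:`CellMatrix` — the cells x metabolite-features intensity matrix,
  tagged with its processing layer (raw → denoised → normalized → log →
  standardized).
* :class:`SCData` — the container tying all layers together with an
  append-only parameter log that supports exact replay.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Any, Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InvariantError, LayerError

LAYERS = ("raw", "denoised", "normalized", "log", "standardized")
_LAYER_RANK = {name: i for i, name in enumerate(LAYERS)}


def _as_float_array(x) -> np.ndarray:
    return np.asarray(x, dtype=np.float64)


@dataclass
class Spectrum:
    """One centroided MS1 acquisition: sorted (m/z, intensity) pairs."""

    scan_index: int
    retention_time: float
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = _as_float_array(self.mz)
        self.intensity = _as_float_array(self.intensity)
        if self.scan_index < 0:
            raise InvariantError(f"scan_index must be >= 0, got {self.scan_index}")
        if self.retention_time < 0:
            raise InvariantError(
                f"retention_time must be >= 0 at scan {self.scan_index}"
            )
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise InvariantError(
                f"mz/intensity length mismatch at scan {self.scan_index}"
            )
        if self.mz.size > 1 and not np.all(np.diff(self.mz) > 0):
            raise InvariantError(
                f"mz values not strictly increasing at scan {self.scan_index}"
            )
        if self.intensity.size and self.intensity.min() < 0:
            raise InvariantError(
                f"negative intensity at scan {self.scan_index}"
            )

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)


@dataclass
class ScanSeries:
    """An ordered scan series (the raw layer of a run)."""

    spectra: list[Spectrum]
    source_files: list[str] = field(default_factory=list)
    polarity: str = "unknown"
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.polarity not in ("positive", "negative", "unknown"):
            raise InvariantError(f"unknown polarity {self.polarity!r}")
        idx = [s.scan_index for s in self.spectra]
        if len(set(idx)) != len(idx):
            seen: set[int] = set()
            for i in idx:
                if i in seen:
                    raise InvariantError(f"duplicated scan_index {i}")
                seen.add(i)
        if any(b <= a for a, b in zip(idx, idx[1:])):
            bad = next(b for a, b in zip(idx, idx[1:]) if b <= a)
            raise InvariantError(f"scan_index not ascending at scan {bad}")
        rts = [s.retention_time for s in self.spectra]
        for a, b, i in zip(rts, rts[1:], idx[1:]):
            if b <= a:
                raise InvariantError(
                    f"retention_time not strictly increasing at scan {i}"
                )

    @property
    def n_scans(self) -> int:
        return len(self.spectra)

    @property
    def scan_indices(self) -> np.ndarray:
        return np.array([s.scan_index for s in self.spectra], dtype=np.int64)

    @property
    def retention_times(self) -> np.ndarray:
        return np.array([s.retention_time for s in self.spectra], dtype=np.float64)

    def total_intensity(self) -> float:
        return float(sum(s.intensity.sum() for s in self.spectra))

    def copy(self) -> "ScanSeries":
        return copy.deepcopy(self)


class PeakTable:
    """Consolidated peaks in long format.

    Parameters
    ----------
    rows
        DataFrame with columns ``scan_index``, ``bin_id``, ``intensity``;
        one row per (scan, bin) with summed member intensity > 0.
    bins
        DataFrame indexed by ``bin_id`` with columns ``representative_mz``
        (intensity-weighted mean m/z), ``member_count`` (raw centroids
        merged into the bin) and ``occurrence`` (distinct scans where the
        bin has positive intensity).
    scan_rt
        Series mapping every scan_index of the source series (including
        scans that ended up empty) to its retention time in seconds.
    """

    def __init__(self, rows: pd.DataFrame, bins: pd.DataFrame, scan_rt: pd.Series):
        self.rows = rows.reset_index(drop=True)
        self.bins = bins
        self.scan_rt = scan_rt
        mz = bins["representative_mz"].to_numpy()
        if mz.size > 1 and not np.all(np.diff(mz) > 0):
            raise InvariantError("representative_mz not strictly increasing with bin_id")

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    @property
    def scan_range(self) -> tuple[int, int]:
        idx = self.scan_rt.index
        return int(idx.min()), int(idx.max())

    def total_intensity(self) -> float:
        return float(self.rows["intensity"].sum())

    def recount_occurrence(self) -> pd.Series:
        """Recompute occurrence from the rows (used by invariant checks)."""
        pos = self.rows[self.rows["intensity"] > 0]
        occ = pos.groupby("bin_id")["scan_index"].nunique()
        return occ.reindex(self.bins.index, fill_value=0)

    def copy(self) -> "PeakTable":
        return PeakTable(self.rows.copy(), self.bins.copy(), self.scan_rt.copy())


@dataclass
class CellEvent:
    """One detected cell transient, with its local-noise window."""

    cell_id: int
    apex_scan: int
    start: int  # inclusive
    end: int  # exclusive
    apex_snr: float
    noise_scans: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (self.start <= self.apex_scan < self.end):
            raise InvariantError(
                f"cell {self.cell_id}: apex {self.apex_scan} outside span "
                f"[{self.start}, {self.end})"
            )
        span = set(range(self.start, self.end))
        if span & set(self.noise_scans):
            raise InvariantError(
                f"cell {self.cell_id}: noise scans overlap the event span"
            )

    @property
    def span_length(self) -> int:
        return self.end - self.start

    def span_scans(self) -> range:
        return range(self.start, self.end)


class CellMatrix:
    """Cells x metabolite-features intensity matrix with layer bookkeeping.

    Rows are cells, columns are features; exports offer a transpose flag.
    ``layer`` tracks where the matrix sits in the processing chain and only
    ever moves forward (raw → denoised → normalized → log → standardized;
    skipping allowed, reversing not).
    """

    def __init__(
        self,
        values: np.ndarray,
        feature_mz: np.ndarray,
        cell_ids: Sequence[int],
        cell_meta: pd.DataFrame,
        layer: str = "raw",
        provenance: list[dict] | None = None,
        log_base: float | None = None,
    ):
        self.values = _as_float_array(values)
        self.feature_mz = _as_float_array(feature_mz)
        self.cell_ids = list(cell_ids)
        self.cell_meta = cell_meta.reset_index(drop=True)
        self.layer = layer
        self.provenance = provenance if provenance is not None else []
        self.log_base = log_base
        self._validate()

    def _validate(self) -> None:
        if self.layer not in _LAYER_RANK:
            raise InvariantError(f"unknown layer {self.layer!r}")
        n_cells, n_feat = self.values.shape
        if len(self.cell_ids) != n_cells or len(self.cell_meta) != n_cells:
            raise InvariantError("cell label count does not match matrix rows")
        if self.feature_mz.size != n_feat:
            raise InvariantError("feature_mz count does not match matrix columns")
        if self.feature_mz.size > 1 and not np.all(np.diff(self.feature_mz) > 0):
            raise InvariantError("feature_mz not strictly increasing")
        if self.layer in ("raw", "denoised") and self.values.size and self.values.min() < 0:
            raise InvariantError(f"negative values in {self.layer} layer")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def advance_layer(self, new_layer: str) -> None:
        """Move the layer tag forward; reversing raises :class:`LayerError`."""
        if _LAYER_RANK[new_layer] < _LAYER_RANK[self.layer]:
            raise LayerError(
                f"cannot move matrix from layer {self.layer!r} back to {new_layer!r}"
            )
        self.layer = new_layer

    def require_layer(self, *allowed: str) -> None:
        if self.layer not in allowed:
            raise LayerError(
                f"operation requires layer in {allowed}, matrix is at {self.layer!r}"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.cell_ids, name="cell_id"),
            columns=[f"{mz:.4f}" for mz in self.feature_mz],
        )

    def copy(self) -> "CellMatrix":
        return CellMatrix(
            self.values.copy(),
            self.feature_mz.copy(),
            list(self.cell_ids),
            self.cell_meta.copy(),
            layer=self.layer,
            provenance=copy.deepcopy(self.provenance),
            log_base=self.log_base,
        )


class SCData:
    """Container for one run: raw scans plus every derived layer.

    ``params`` is an append-only log of every operation applied, in order;
    :func:`replay` re-runs it against the stored raw layer and must
    reproduce the current matrix (pipeline stages are deterministic).
    """

    def __init__(self, raw: ScanSeries):
        if not isinstance(raw, ScanSeries):
            raise InvariantError("SCData requires a ScanSeries raw layer")
        self.raw = raw
        self.peaks: PeakTable | None = None
        self.series: ScanSeries = raw  # working (possibly cut/offset) series
        self.cells: list[CellEvent] | None = None
        self.matrix: CellMatrix | None = None
        self.params: list[dict[str, Any]] = []

    def log(self, op: str, **params: Any) -> None:
        self.params.append({"op": op, "params": params})


def new_scdata(series: ScanSeries) -> SCData:
    """Wrap a validated scan series into a fresh :class:`SCData`."""
    return SCData(series)


def replay(scdata: SCData) -> SCData:
    """Re-run the logged operations on the stored raw layer.

    Returns a fresh :class:`SCData` whose state must match ``scdata``
    (bit-for-bit for the deterministic pipeline stages).
    """
    from .pipeline import apply_stage  # late import: pipeline depends on model

    if scdata.raw is None:
        raise InvariantError("cannot replay: raw layer missing (unrecoverable state)")
    if not scdata.params:
        raise InvariantError("cannot replay: params log is empty")
    fresh = SCData(scdata.raw.copy())
    for entry in scdata.params:
        apply_stage(fresh, entry["op"], dict(entry["params"]))
    return fresh


def concat_series(parts: Iterable[ScanSeries]) -> ScanSeries:
    """Concatenate scan series end to end.

    Scan indices are renumbered consecutively; retention times of later
    parts are shifted so the combined series stays strictly increasing,
    with the gap between parts set to the median inter-scan interval of
    the material so far.
    """
    parts = list(parts)
    if not parts:
        raise InvariantError("nothing to concatenate")
    spectra: list[Spectrum] = []
    sources: list[str] = []
    meta: dict[str, Any] = {}
    polarity = parts[0].polarity
    next_index = 0
    t_offset = 0.0
    last_rt = None
    for part in parts:
        rts = part.retention_times
        if len(spectra) and rts.size:
            all_rt = np.array([s.retention_time for s in spectra])
            dts = np.diff(all_rt)
            gap = float(np.median(dts)) if dts.size else 1.0
            t_offset = last_rt + gap - rts[0]
        for s in part.spectra:
            spectra.append(
                Spectrum(next_index, s.retention_time + t_offset, s.mz.copy(), s.intensity.copy())
            )
            next_index += 1
        if spectra:
            last_rt = spectra[-1].retention_time
        sources.extend(part.source_files)
        meta.update(part.meta)
        if part.polarity != polarity:
            polarity = "unknown"
    return ScanSeries(spectra, source_files=sources, polarity=polarity, meta=meta)
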