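"""In-silico flow-injection single-cell metabolomics runs with ground truth.

The generator emulates the signal structure of a time-series SCM
acquisition: a steady chemical background of contaminant ions, sparse
random chemical noise, and short Gaussian-shaped cell transients (a few
scans wide) whose metabolite panels are cell-type specific. Every quantity
the pipeline later estimates — background levels, cell apex positions and
spans, per-metabolite integrated intensities, any injected m/z drift — is
recorded in a :class:`GroundTruth` object so each processing stage can be
scored against what was actually programmed.

What the simulator deliberately does *not* model: isotope envelopes,
multiple charge states, detector saturation, retention-time-dependent
matrix effects, and peak-shape asymmetry. Conclusions drawn from it speak
to the correctness of the processing arithmetic, not to instrument
physics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvariantError
from .model import CellEvent, ScanSeries, Spectrum

# Default background contaminant ions (m/z, mean counts/scan). 445.1200 is
# the classic polysiloxane lock-mass region seen in positive-mode runs.
# Levels are modest relative to cell signals: in flow-injection SCM the
# transient of a whole cell dominates the ambient chemical background —
# that contrast is what makes TIC-based cell detection possible at all.
DEFAULT_BACKGROUND = [
    (104.1070, 120.0),
    (147.0764, 90.0),
    (229.1491, 70.0),
    (279.0932, 60.0),
    (301.1411, 50.0),
    (371.1012, 45.0),
    (445.1200, 150.0),
    (519.1388, 40.0),
]

# Two cell types sharing six metabolites and carrying six private ones
# each: separable structure for embedding tests, shared features for
# prevalence tests. Tuples are (m/z, mean amplitude, lognormal sigma).
_SHARED_PANEL = [
    (90.0549, 2600.0, 0.3),
    (118.0862, 2000.0, 0.3),
    (132.1019, 2300.0, 0.3),
    (156.0768, 1800.0, 0.3),
    (175.1190, 3000.0, 0.3),
    (203.0526, 2100.0, 0.3),
]
_TYPE_A_PANEL = [
    (86.0964, 2400.0, 0.3),
    (122.0270, 1900.0, 0.3),
    (148.0604, 2700.0, 0.3),
    (166.0863, 2000.0, 0.3),
    (184.0733, 2200.0, 0.3),
    (205.0972, 2500.0, 0.3),
]
_TYPE_B_PANEL = [
    (104.0706, 2500.0, 0.3),
    (130.0499, 2000.0, 0.3),
    (150.0583, 2800.0, 0.3),
    (170.0924, 1900.0, 0.3),
    (188.0703, 2200.0, 0.3),
    (219.0260, 2400.0, 0.3),
]

DEFAULT_CELL_TYPES = [
    ("A", _SHARED_PANEL + _TYPE_A_PANEL),
    ("B", _SHARED_PANEL + _TYPE_B_PANEL),
]

DEFAULT_DEBRIS_PANEL = [
    (239.0631, 3600.0, 0.3),
    (268.1043, 3400.0, 0.3),
]


@dataclass
class SimConfig:
    """Parameters of one simulated run.

    Amplitudes and background levels are ion counts per scan; m/z in Th;
    pulse widths in scans. Cell apex times are rejection-sampled to keep
    neighbouring apexes at least ``4 * pulse_sigma`` scans apart.
    """

    n_scans: int = 3000
    dt: float = 0.2  # seconds per scan
    n_cells: int = 50
    cell_types: list[tuple[str, list[tuple[float, float, float]]]] = field(
        default_factory=lambda: [(t, list(p)) for t, p in DEFAULT_CELL_TYPES]
    )
    background_bins: list[tuple[float, float]] = field(
        default_factory=lambda: list(DEFAULT_BACKGROUND)
    )
    chemical_noise_rate: float = 5.0  # spurious peaks per scan
    chemical_noise_mean: float = 100.0  # mean intensity of a spurious peak
    noise_mz_range: tuple[float, float] = (60.0, 600.0)
    pulse_sigma: float = 1.5  # scans
    amplitude_lognormal_sigma: float = 0.25  # per-cell size factor
    mz_jitter_sd: float = 0.001  # Th, per emitted centroid
    drift_delta: float = 0.0  # constant m/z shift applied to everything
    apex_window_s: tuple[float, float] = (100.0, 500.0)
    n_debris: int = 0
    debris_panel: list[tuple[float, float, float]] = field(
        default_factory=lambda: list(DEFAULT_DEBRIS_PANEL)
    )
    batch_labels: list[str] = field(default_factory=lambda: ["batch0"])
    batch_intensity_scale: list[float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_scans < 1 or self.dt <= 0:
            raise InvariantError("n_scans must be >= 1 and dt > 0")
        if self.pulse_sigma < 0 or self.mz_jitter_sd < 0:
            raise InvariantError("sigmas must be >= 0")
        if self.chemical_noise_rate < 0 or self.chemical_noise_mean < 0:
            raise InvariantError("noise rates must be >= 0")
        if self.amplitude_lognormal_sigma < 0:
            raise InvariantError("amplitude_lognormal_sigma must be >= 0")
        if self.batch_intensity_scale is None:
            self.batch_intensity_scale = [1.0] * len(self.batch_labels)
        if len(self.batch_intensity_scale) != len(self.batch_labels):
            raise InvariantError("one intensity scale per batch label required")


@dataclass
class GroundTruth:
    """Everything the generator programmed, for scoring recovery.

    ``cells`` has one row per transient (including debris) with its apex
    scan, emitted scan support, type/batch label and per-cell size factor;
    ``cell_intensities`` maps truth cell id -> {metabolite m/z -> emitted
    integrated intensity} (post batch scaling, pre m/z jitter).
    """

    cells: pd.DataFrame
    cell_intensities: dict[int, dict[float, float]]
    background_levels: dict[float, float]
    drift_delta: float
    tic_background: float  # expected (mean) cell-free TIC per scan
    tic_background_median: float  # median TIC over the emitted cell-free scans
    batch_of_scan: np.ndarray
    config: SimConfig


def _sample_apexes(rng: np.random.Generator, cfg: SimConfig, n: int) -> np.ndarray:
    lo = int(np.ceil(cfg.apex_window_s[0] / cfg.dt))
    hi = int(np.floor(cfg.apex_window_s[1] / cfg.dt))
    hi = min(hi, cfg.n_scans - 1)
    if hi <= lo:
        raise InvariantError("apex window contains no scans")
    min_sep = max(1, int(np.ceil(4 * cfg.pulse_sigma)))
    chosen: list[int] = []
    attempts = 0
    while len(chosen) < n:
        cand = int(rng.integers(lo, hi + 1))
        if all(abs(cand - c) >= min_sep for c in chosen):
            chosen.append(cand)
        attempts += 1
        if attempts > 1000 * max(n, 1):
            raise InvariantError(
                "could not place cell apexes with the required separation; "
                "reduce n_cells or widen the apex window"
            )
    return np.array(sorted(chosen), dtype=np.int64)


def simulate_run(config: SimConfig) -> tuple[ScanSeries, GroundTruth]:
    """Generate a reproducible synthetic run and its ground truth."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_scans

    # batch structure: the run is split into equal time segments
    n_batches = len(cfg.batch_labels)
    batch_of_scan = np.minimum(
        (np.arange(n) * n_batches) // n, n_batches - 1
    ).astype(np.int64)
    scan_scale = np.asarray(cfg.batch_intensity_scale, dtype=float)[batch_of_scan]

    scans: list[np.ndarray] = []
    mzs: list[np.ndarray] = []
    intens: list[np.ndarray] = []

    def _emit(scan_arr, mz_arr, int_arr, jitter=True):
        mz_arr = np.asarray(mz_arr, dtype=float) + cfg.drift_delta
        if jitter and cfg.mz_jitter_sd > 0:
            mz_arr = mz_arr + rng.normal(0.0, cfg.mz_jitter_sd, size=mz_arr.size)
        keep = np.asarray(int_arr, dtype=float) > 0
        scans.append(np.asarray(scan_arr, dtype=np.int64)[keep])
        mzs.append(mz_arr[keep])
        intens.append(np.asarray(int_arr, dtype=float)[keep])

    # 1. background contaminant ions: Poisson counts around programmed level
    for bmz, level in cfg.background_bins:
        counts = rng.poisson(level * scan_scale).astype(float)
        _emit(np.arange(n), np.full(n, bmz), counts)

    # 2. chemical noise: Poisson number of spurious peaks per scan,
    #    uniform m/z, exponential intensity
    if cfg.chemical_noise_rate > 0:
        per_scan = rng.poisson(cfg.chemical_noise_rate, size=n)
        total = int(per_scan.sum())
        noise_scans = np.repeat(np.arange(n), per_scan)
        noise_mz = rng.uniform(*cfg.noise_mz_range, size=total)
        noise_int = rng.exponential(cfg.chemical_noise_mean, size=total)
        noise_int *= scan_scale[noise_scans]
        _emit(noise_scans, noise_mz, noise_int, jitter=False)

    # 3. cell transients (plus optional low-content debris)
    n_events = cfg.n_cells + cfg.n_debris
    apexes = _sample_apexes(rng, cfg, n_events) if n_events else np.array([], dtype=np.int64)
    if n_events:
        is_debris = np.zeros(n_events, dtype=bool)
        if cfg.n_debris:
            debris_idx = rng.choice(n_events, size=cfg.n_debris, replace=False)
            is_debris[debris_idx] = True
    half = max(1, int(np.ceil(4 * cfg.pulse_sigma)))

    truth_rows = []
    cell_intensities: dict[int, dict[float, float]] = {}
    for tid in range(n_events):
        apex = int(apexes[tid])
        if is_debris[tid]:
            label, panel = "debris", cfg.debris_panel
        else:
            label, panel = cfg.cell_types[tid % len(cfg.cell_types)]
        support = np.arange(max(0, apex - half), min(n, apex + half + 1))
        if cfg.pulse_sigma > 0:
            weights = np.exp(-0.5 * ((support - apex) / cfg.pulse_sigma) ** 2)
        else:
            weights = (support == apex).astype(float)
        cell_scale = float(
            rng.lognormal(0.0, cfg.amplitude_lognormal_sigma)
        )
        per_met: dict[float, float] = {}
        for pmz, mean_amp, lsig in panel:
            # mean-preserving lognormal variation per metabolite
            amp = mean_amp * cell_scale * float(
                rng.lognormal(-0.5 * lsig**2, lsig)
            )
            vals = amp * weights * scan_scale[support]
            _emit(support, np.full(support.size, pmz), vals)
            per_met[pmz] = float(vals.sum())
        cell_intensities[tid] = per_met
        truth_rows.append(
            {
                "truth_id": tid,
                "apex_scan": apex,
                "start_scan": int(support[0]),
                "end_scan": int(support[-1]) + 1,
                "type": label,
                "batch": cfg.batch_labels[int(batch_of_scan[apex])],
                "cell_scale": cell_scale,
                "is_debris": bool(is_debris[tid]),
            }
        )

    # assemble per-scan sorted spectra
    all_scan = np.concatenate(scans) if scans else np.array([], dtype=np.int64)
    all_mz = np.concatenate(mzs) if mzs else np.array([])
    all_int = np.concatenate(intens) if intens else np.array([])
    order = np.lexsort((all_mz, all_scan))
    all_scan, all_mz, all_int = all_scan[order], all_mz[order], all_int[order]

    spectra = []
    bounds = np.searchsorted(all_scan, np.arange(n + 1))
    for s in range(n):
        lo, hi = bounds[s], bounds[s + 1]
        mz_s, int_s = all_mz[lo:hi], all_int[lo:hi]
        if mz_s.size > 1:
            # merge exact m/z ties within a scan so spectra stay strictly sorted
            uniq, inv = np.unique(mz_s, return_inverse=True)
            if uniq.size != mz_s.size:
                int_s = np.bincount(inv, weights=int_s)
                mz_s = uniq
        spectra.append(Spectrum(s, s * cfg.dt, mz_s, int_s))

    series = ScanSeries(
        spectra,
        source_files=[f"simulated(seed={cfg.seed})"],
        polarity="positive",
        meta={"sim_seed": cfg.seed},
    )
    tic = np.array([sp.intensity.sum() for sp in spectra])
    cell_free = np.ones(n, dtype=bool)
    for row in truth_rows:
        cell_free[row["start_scan"] : row["end_scan"]] = False
    tic_median = float(np.median(tic[cell_free])) if cell_free.any() else 0.0
    truth = GroundTruth(
        cells=pd.DataFrame(
            truth_rows,
            columns=[
                "truth_id", "apex_scan", "start_scan", "end_scan",
                "type", "batch", "cell_scale", "is_debris",
            ],
        ),
        cell_intensities=cell_intensities,
        background_levels={mz: level for mz, level in cfg.background_bins},
        drift_delta=cfg.drift_delta,
        tic_background=sum(l for _, l in cfg.background_bins)
        + cfg.chemical_noise_rate * cfg.chemical_noise_mean,
        tic_background_median=tic_median,
        batch_of_scan=batch_of_scan,
        config=cfg,
    )
    return series, truth


def score_detection(
    events: list[CellEvent], truth: GroundTruth
) -> tuple[float, float, list[tuple[int, int]]]:
    """Greedy one-to-one matching of detections to programmed transients.

    A detection matches a truth cell if their scan spans overlap by at
    least one scan; pairs are matched greedily by overlap length. Returns
    ``(recall, precision, matched pairs)`` where pairs are
    ``(cell_id, truth_id)``.
    """
    n_truth = len(truth.cells)
    n_det = len(events)
    if n_truth == 0:
        return 1.0, (1.0 if n_det == 0 else 0.0), []
    if n_det == 0:
        return 0.0, 1.0, []
    cand = []
    for ev in events:
        for row in truth.cells.itertuples():
            ov = min(ev.end, row.end_scan) - max(ev.start, row.start_scan)
            if ov > 0:
                cand.append((ov, ev.cell_id, row.truth_id))
    cand.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_det: set[int] = set()
    used_truth: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for _, det_id, truth_id in cand:
        if det_id in used_det or truth_id in used_truth:
            continue
        used_det.add(det_id)
        used_truth.add(truth_id)
        pairs.append((det_id, truth_id))
    recall = len(pairs) / n_truth
    precision = len(pairs) / n_det
    return recall, precision, pairs
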