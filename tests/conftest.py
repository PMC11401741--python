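"""Shared fixtures: small hand-built series and cached synthetic runs."""

from __future__ import annotations

import numpy as np
import pytest

from scmpipe import (
    DetectionParams,
    SimConfig,
    Spectrum,
    ScanSeries,
    compute_tic,
    consolidate_mz,
    detect_cells,
    estimate_noise,
    filter_occurrences,
    merge_cells,
    screen_and_subtract,
    score_detection,
    simulate_run,
)


def make_series(peaks_per_scan, dt=1.0, polarity="unknown"):
    """Build a ScanSeries from [(mz, intensity), ...] lists per scan."""
    spectra = []
    for i, peaks in enumerate(peaks_per_scan):
        peaks = sorted(peaks)
        mz = np.array([p[0] for p in peaks], dtype=float)
        inten = np.array([p[1] for p in peaks], dtype=float)
        spectra.append(Spectrum(i, i * dt, mz, inten))
    return ScanSeries(spectra, polarity=polarity)


def random_series(seed: int, n_scans: int = 50, max_peaks: int = 30) -> ScanSeries:
    rng = np.random.default_rng(seed)
    spectra = []
    for i in range(n_scans):
        n = int(rng.integers(0, max_peaks))
        mz = np.unique(rng.uniform(60, 600, n))
        spectra.append(Spectrum(i, i * 0.2, mz, rng.exponential(100, mz.size)))
    return ScanSeries(spectra, polarity="positive")


def nearest_bin(bins_mz: np.ndarray, target: float, tol: float = 0.02) -> int | None:
    """Index of the bin whose representative m/z is nearest to target."""
    j = int(np.argmin(np.abs(bins_mz - target)))
    return j if abs(bins_mz[j] - target) <= tol else None


@pytest.fixture(scope="session")
def sim1():
    """Default-condition synthetic run, seed 1 (do not mutate)."""
    return simulate_run(SimConfig(seed=1))


@pytest.fixture(scope="session")
def table1(sim1):
    series, _ = sim1
    return filter_occurrences(consolidate_mz(series), 10)


@pytest.fixture(scope="session")
def events1(table1):
    trace = compute_tic(table1)
    return detect_cells(trace, DetectionParams())


@pytest.fixture(scope="session")
def denoised1(table1, events1):
    raw = merge_cells(table1, events1)
    profiles = [estimate_noise(table1, ev) for ev in events1]
    return screen_and_subtract(raw, profiles)


@pytest.fixture(scope="session")
def matched1(sim1, events1):
    """Mapping detected cell_id -> truth_id for the seed-1 run."""
    _, truth = sim1
    _, _, pairs = score_detection(events1, truth)
    return dict(pairs)
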