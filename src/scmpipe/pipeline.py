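"""One-command orchestration of the full processing pipeline.

Stage order is fixed: import → cut → offset → consolidate → occurrence
filter → detect → merge → local-noise screen/subtract → cell-matrix
filter → prevalence filter → normalize → log/standardize. Stages are
individually skippable by config flag but never reorderable, which keeps
the params log replayable. Every stage appends exactly one entry to
``SCData.params``.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Any, Callable

import yaml

from . import detect as _detect
from . import matrix as _matrix
from . import msio, noise, preprocess
from .errors import ConfigError, EmptyRunError
from .model import SCData, ScanSeries, new_scdata

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict[str, dict[str, Any]] = {
    "input": {"format": "csv", "paths": [], "sim_seed": None},
    "cut": {"enabled": False, "t_start": 0.0, "t_end": None},
    "offset": {
        "enabled": False,
        "mode": "estimate",  # or "fixed"
        "reference_mz": None,
        "tol": 0.02,
        "delta_mz": 0.0,
    },
    "consolidate": {"resolution": 0.01},
    "occurrence": {"enabled": True, "min_occurrence": 10},
    "detect": {
        "snr_threshold": 3.0,
        "baseline_window": 51,
        "smooth_window": 3,
        "max_halfwidth": 10,
        "min_separation": 2,
        "noise_margin": 5,
    },
    "merge": {"batch_windows": []},  # list of [t_start, t_end, label]
    "noise": {"enabled": True, "snr_threshold": 3.0},
    "cell_filter": {"enabled": True, "min_features": 10},
    "prevalence": {"enabled": True, "min_fraction": 0.15},
    "normalize": {"enabled": True, "method": "total"},
    "log": {
        "enabled": True,
        "log_base": "e",
        "pseudo_count": 1.0,
        "standardize": True,
        "batch_center": False,
    },
    "output": {"bundle": None},
}


def make_config(overrides: dict | None = None) -> dict:
    """Materialize a full config from defaults plus nested overrides.

    Unknown sections or keys are rejected so typos never silently fall
    back to defaults.
    """
    cfg = {k: dict(v) for k, v in DEFAULT_CONFIG.items()}
    for section, values in (overrides or {}).items():
        if section not in cfg:
            raise ConfigError(f"unknown config section {section!r}")
        if not isinstance(values, dict):
            raise ConfigError(f"config section {section!r} must be a mapping")
        for key, val in values.items():
            if key not in cfg[section]:
                raise ConfigError(f"unknown key {section}.{key}")
            cfg[section][key] = val
    return cfg


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return make_config(data)


# ------------------------------------------------------------- stages
#
# Each stage is a function (SCData, params) -> None mutating the SCData;
# `apply_stage` dispatches by name and is what `replay` uses. Stages log
# themselves exactly once.


def _stage_cut(scd: SCData, p: dict) -> None:
    scd.series = preprocess.cut(scd.series, p["t_start"], p["t_end"])


def _stage_offset(scd: SCData, p: dict) -> None:
    if p["mode"] == "estimate":
        model = preprocess.estimate_offset(scd.series, p["reference_mz"], p["tol"])
    elif p["mode"] == "fixed":
        model = preprocess.OffsetModel(delta_mz=p["delta_mz"])
    else:
        raise ConfigError(f"unknown offset mode {p['mode']!r}")
    scd.series = preprocess.apply_offset(scd.series, model)


def _stage_consolidate(scd: SCData, p: dict) -> None:
    scd.peaks = preprocess.consolidate_mz(scd.series, p["resolution"])


def _stage_occurrence(scd: SCData, p: dict) -> None:
    scd.peaks = preprocess.filter_occurrences(scd.peaks, p["min_occurrence"])


def _stage_detect(scd: SCData, p: dict) -> None:
    params = _detect.DetectionParams(**p)
    trace = _detect.compute_tic(scd.peaks, params.baseline_window)
    scd.cells = _detect.detect_cells(trace, params)
    if not scd.cells:
        raise EmptyRunError(
            "no cell events detected; review the cut window and detection "
            "parameters"
        )


def _stage_merge(scd: SCData, p: dict) -> None:
    scd.matrix = _detect.merge_cells(scd.peaks, scd.cells)
    windows = p.get("batch_windows") or []
    if windows:
        meta = scd.matrix.cell_meta
        for t0, t1, label in windows:
            mask = (meta["apex_rt_s"] >= t0) & (meta["apex_rt_s"] < t1)
            meta.loc[mask, "batch"] = label


def _stage_noise(scd: SCData, p: dict) -> None:
    profiles = [noise.estimate_noise(scd.peaks, ev) for ev in scd.cells]
    scd.matrix = noise.screen_and_subtract(scd.matrix, profiles, p["snr_threshold"])


def _stage_cell_filter(scd: SCData, p: dict) -> None:
    scd.matrix = _detect.filter_cell_matrix(scd.matrix, p["min_features"])
    kept = set(scd.matrix.cell_ids)
    scd.cells = [ev for ev in scd.cells if ev.cell_id in kept]


def _stage_prevalence(scd: SCData, p: dict) -> None:
    scd.matrix = _matrix.prevalence_filter(scd.matrix, p["min_fraction"])


def _stage_normalize(scd: SCData, p: dict) -> None:
    scd.matrix = _matrix.normalize(
        scd.matrix, _matrix.NormalizationSpec(method=p["method"])
    )


def _stage_log(scd: SCData, p: dict) -> None:
    spec = _matrix.NormalizationSpec(
        log_base=p["log_base"],
        pseudo_count=p["pseudo_count"],
        standardize=p["standardize"],
        batch_center=p["batch_center"],
    )
    scd.matrix = _matrix.log_standardize(scd.matrix, spec)


STAGES: dict[str, Callable[[SCData, dict], None]] = {
    "cut": _stage_cut,
    "offset": _stage_offset,
    "consolidate": _stage_consolidate,
    "occurrence": _stage_occurrence,
    "detect": _stage_detect,
    "merge": _stage_merge,
    "noise": _stage_noise,
    "cell_filter": _stage_cell_filter,
    "prevalence": _stage_prevalence,
    "normalize": _stage_normalize,
    "log": _stage_log,
}

STAGE_ORDER = list(STAGES)


def apply_stage(scd: SCData, name: str, params: dict) -> None:
    """Run one named stage and append it to the params log."""
    if name not in STAGES:
        raise ConfigError(f"unknown stage {name!r}")
    STAGES[name](scd, params)
    scd.log(name, **params)


def _stage_params(cfg_section: dict) -> dict:
    return {k: v for k, v in cfg_section.items() if k != "enabled"}


def run_pipeline(
    config: dict | None = None, series: ScanSeries | None = None
) -> tuple[SCData, dict]:
    """Execute the full pipeline; returns the SCData and a run report.

    ``series`` may be passed directly (e.g. a simulated run); otherwise
    the input section of the config decides what to read.
    """
    cfg = make_config(config)
    if series is None:
        inp = cfg["input"]
        if inp["sim_seed"] is not None:
            from .simulate import SimConfig, simulate_run

            series, _ = simulate_run(SimConfig(seed=int(inp["sim_seed"])))
        elif inp["format"] == "csv":
            series = msio.read_long_csv(inp["paths"])
        elif inp["format"] == "mzml":
            parts = [msio.read_mzml(p) for p in inp["paths"]]
            series = parts[0] if len(parts) == 1 else msio.concat_series(parts)
        else:
            raise ConfigError(f"unknown input format {inp['format']!r}")

    scd = new_scdata(series)
    report: dict[str, Any] = {"stages": [], "n_scans_in": series.n_scans}

    def _counts(scd: SCData) -> dict:
        out: dict[str, Any] = {}
        out["n_scans"] = scd.series.n_scans
        if scd.peaks is not None:
            out["n_bins"] = scd.peaks.n_bins
        if scd.cells is not None:
            out["n_cells"] = len(scd.cells)
        if scd.matrix is not None:
            out["matrix_shape"] = list(scd.matrix.values.shape)
            out["layer"] = scd.matrix.layer
        return out

    for name in STAGE_ORDER:
        section = cfg[name] if name in cfg else {}
        if name == "cut" and not section.get("enabled", False):
            continue
        if name == "offset" and not section.get("enabled", False):
            continue
        if not section.get("enabled", True):
            continue
        params = _stage_params(section)
        if name == "cut" and params.get("t_end") is None:
            params["t_end"] = float(scd.series.retention_times[-1]) + 1.0
        t0 = time.perf_counter()
        try:
            apply_stage(scd, name, params)
        except Exception:
            logger.error("stage %r failed with params %s", name, params)
            raise
        entry = {
            "stage": name,
            "params": params,
            "duration_s": round(time.perf_counter() - t0, 4),
            **_counts(scd),
        }
        report["stages"].append(entry)
        logger.info(
            "stage %-12s %s", name,
            {k: v for k, v in entry.items() if k not in ("stage", "params")},
        )

    report["params_log"] = scd.params
    bundle = cfg["output"]["bundle"]
    if bundle:
        msio.save_bundle(scd, bundle)
        Path(bundle, "report.json").write_text(
            json.dumps(report, indent=2, default=str)
        )
    return scd, report
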