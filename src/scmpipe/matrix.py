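"""Prevalence filtering, normalization, log transform and standardization
of the cells x features matrix.

The order contract follows the pipeline: prevalence filter on the
denoised layer, then normalization, then log + z-scoring. Normalization
targets (cohort medians) keep values on an interpretable intensity scale
instead of rescaling to 1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .errors import EmptyMatrixError, InvariantError
from .model import CellMatrix

logger = logging.getLogger(__name__)

_LOG_BASES = {"e": math.e, "2": 2.0, "10": 10.0}


@dataclass
class NormalizationSpec:
    """How to normalize, transform and standardize the matrix.

    ``method``: ``total`` (row sums equalized to the cohort median sum),
    ``median`` (per-cell median of nonzero values equalized), ``pqn``
    (probabilistic quotient against the cohort-median reference profile)
    or ``none``. ``log_base`` is one of ``e``/``2``/``10``;
    ``pseudo_count`` is added before the log so zeros stay finite.
    ``batch_center`` subtracts the per-batch median of each feature on
    the log scale before z-scoring.
    """

    method: str = "total"
    log_base: str = "e"
    pseudo_count: float = 1.0
    standardize: bool = True
    batch_center: bool = False

    def __post_init__(self) -> None:
        if self.method not in ("total", "median", "pqn", "none"):
            raise InvariantError(f"unknown normalization method {self.method!r}")
        if str(self.log_base) not in _LOG_BASES:
            raise InvariantError(f"log_base must be one of {list(_LOG_BASES)}")
        self.log_base = str(self.log_base)
        if self.pseudo_count <= 0:
            raise InvariantError("pseudo_count must be > 0")


def prevalence_filter(matrix: CellMatrix, min_fraction: float = 0.15) -> CellMatrix:
    """Keep features detected (nonzero) in at least ``min_fraction`` of cells.

    The 10%-20% band is the practical range for separating real cell
    metabolites from sporadic background; the default sits at its
    midpoint. Boundary semantics: a feature exactly at the threshold
    survives.
    """
    if not (0 < min_fraction <= 1):
        raise InvariantError("min_fraction must be in (0, 1]")
    matrix.require_layer("denoised")
    frac = (matrix.values > 0).mean(axis=0)
    keep = frac >= min_fraction
    if not keep.any():
        raise EmptyMatrixError(
            f"prevalence filter at {min_fraction:.0%} removed every feature; "
            "review denoising and detection parameters"
        )
    logger.info(
        "prevalence filter (>= %.0f%%): kept %d of %d features",
        100 * min_fraction, int(keep.sum()), matrix.n_features,
    )
    out = CellMatrix(
        matrix.values[:, keep],
        matrix.feature_mz[keep],
        list(matrix.cell_ids),
        matrix.cell_meta.copy(),
        layer=matrix.layer,
        provenance=list(matrix.provenance),
        log_base=matrix.log_base,
    )
    out.provenance.append(
        {
            "op": "prevalence_filter",
            "min_fraction": min_fraction,
            "removed": int((~keep).sum()),
        }
    )
    return out


def normalize(matrix: CellMatrix, spec: NormalizationSpec | None = None) -> CellMatrix:
    """Per-cell scaling to remove cell-to-cell measurement variation."""
    spec = spec or NormalizationSpec()
    matrix.require_layer("denoised")
    values = matrix.values
    row_sums = values.sum(axis=1)
    alive = row_sums > 0
    if not alive.all():
        dropped = [cid for cid, a in zip(matrix.cell_ids, alive) if not a]
        logger.warning("normalize: dropping %d all-zero cells: %s", len(dropped), dropped)
    if not alive.any():
        raise EmptyMatrixError("normalize: every cell has an all-zero row")
    values = values[alive]
    cell_ids = [cid for cid, a in zip(matrix.cell_ids, alive) if a]
    meta = matrix.cell_meta.loc[alive].reset_index(drop=True)

    if spec.method == "none":
        scaled = values.copy()
    elif spec.method == "total":
        sums = values.sum(axis=1)
        target = float(np.median(sums))
        scaled = values * (target / sums)[:, None]
    elif spec.method == "median":
        med = np.array(
            [float(np.median(row[row > 0])) for row in values]
        )
        target = float(np.median(med))
        scaled = values * (target / med)[:, None]
    else:  # pqn
        reference = np.median(values, axis=0)
        ref_pos = reference > 0
        if not ref_pos.any():
            raise EmptyMatrixError("pqn: cohort-median reference profile is all zero")
        quotients = values[:, ref_pos] / reference[ref_pos]
        scale = np.array([float(np.median(q)) for q in quotients])
        if (scale <= 0).any():
            raise EmptyMatrixError("pqn: a cell has a non-positive quotient median")
        scaled = values / scale[:, None]

    out = CellMatrix(
        scaled,
        matrix.feature_mz,
        cell_ids,
        meta,
        layer="denoised",  # validated non-negative, then advanced
        provenance=list(matrix.provenance),
        log_base=matrix.log_base,
    )
    out.advance_layer("normalized")
    out.provenance.append({"op": "normalize", "method": spec.method})
    return out


def log_standardize(matrix: CellMatrix, spec: NormalizationSpec | None = None) -> CellMatrix:
    """Log-transform and optionally batch-center and z-score per feature.

    ``x -> log_base(x + pseudo_count)``; with ``batch_center``, each
    feature's per-batch median (log scale) is subtracted; with
    ``standardize``, each feature is z-scored across cells (constant
    features are set to 0).
    """
    spec = spec or NormalizationSpec()
    matrix.require_layer("denoised", "normalized")
    base = _LOG_BASES[spec.log_base]
    logged = np.log(matrix.values + spec.pseudo_count) / math.log(base)

    if spec.batch_center:
        if "batch" not in matrix.cell_meta.columns:
            raise InvariantError("batch_center requires a 'batch' cell-meta column")
        batches = matrix.cell_meta["batch"].to_numpy()
        for b in np.unique(batches):
            rows = batches == b
            logged[rows] -= np.median(logged[rows], axis=0)

    final_layer = "log"
    if spec.standardize:
        mean = logged.mean(axis=0)
        sd = logged.std(axis=0, ddof=0)
        # a numerically constant feature has sd at rounding level, not 0
        nonconst = sd > 1e-12 * np.maximum(1.0, np.abs(mean))
        logged = logged - mean
        logged[:, nonconst] /= sd[nonconst]
        logged[:, ~nonconst] = 0.0
        final_layer = "standardized"

    out = CellMatrix(
        logged,
        matrix.feature_mz,
        list(matrix.cell_ids),
        matrix.cell_meta.copy(),
        layer="log",
        provenance=list(matrix.provenance),
        log_base=base,
    )
    if final_layer == "standardized":
        out.advance_layer("standardized")
    out.provenance.append(
        {
            "op": "log_standardize",
            "log_base": spec.log_base,
            "pseudo_count": spec.pseudo_count,
            "standardize": spec.standardize,
            "batch_center": spec.batch_center,
        }
    )
    return out
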