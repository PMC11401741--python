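"""Exact-mass metabolite annotation against a local mass table.

Features are matched to ``monoisotopic_mass + adduct shift`` within a ppm
tolerance. The table is any TSV with columns ``id, name, formula,
monoisotopic_mass`` (an HMDB export works); a small bundled table of
common central-carbon metabolites ships for tests and the demo — it is
not an HMDB extract, its masses are computed from the formulas.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .elements import ADDUCT_SHIFTS
from .errors import InvariantError

REQUIRED_COLUMNS = ["id", "name", "formula", "monoisotopic_mass"]


@dataclass(frozen=True)
class MassRecord:
    record_id: str
    name: str
    formula: str
    monoisotopic_mass: float

    def __post_init__(self) -> None:
        if self.monoisotopic_mass <= 0:
            raise InvariantError(
                f"record {self.record_id}: monoisotopic_mass must be > 0"
            )


@dataclass(frozen=True)
class AnnotationHit:
    feature_mz: float
    record_id: str
    name: str
    adduct: str
    theoretical_mz: float
    ppm_error: float


def builtin_mass_table_path() -> Path:
    """Path of the bundled mini mass table (for tests and the demo)."""
    return Path(resources.files("scmpipe").joinpath("data/builtin_masses.tsv"))


def load_mass_table(path: str | Path) -> list[MassRecord]:
    """Load and validate a mass-table TSV, sorted by mass."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise InvariantError(f"mass table {path}: missing columns {missing}")
    if not pd.api.types.is_numeric_dtype(df["monoisotopic_mass"]):
        raise InvariantError(f"mass table {path}: unparsable monoisotopic_mass column")
    dup = df["id"][df["id"].duplicated()]
    if len(dup):
        raise InvariantError(f"mass table {path}: duplicate id {dup.iloc[0]!r}")
    df = df.sort_values("monoisotopic_mass", kind="stable")
    return [
        MassRecord(str(r.id), str(r.name), str(r.formula), float(r.monoisotopic_mass))
        for r in df.itertuples()
    ]


def default_adducts(polarity: str) -> list[str]:
    if polarity == "negative":
        return ["[M-H]-"]
    return ["[M+H]+", "[M+Na]+", "[M+K]+"]


def annotate(
    features: list[float] | np.ndarray,
    records: list[MassRecord],
    adducts: list[str] | None = None,
    tol_ppm: float = 10.0,
    polarity: str = "positive",
) -> list[AnnotationHit]:
    """Match feature m/z values to records within a ppm tolerance.

    All (record, adduct) combinations within ``tol_ppm`` are reported;
    hits for one feature are ranked by absolute ppm error. Lookup uses a
    binary search over the sorted theoretical m/z values.
    """
    if adducts is None:
        adducts = default_adducts(polarity)
    for a in adducts:
        if a not in ADDUCT_SHIFTS:
            raise InvariantError(f"unknown adduct {a!r}")
        shift_polarity = ADDUCT_SHIFTS[a][1]
        if shift_polarity != polarity:
            raise InvariantError(
                f"adduct {a} is a {shift_polarity}-mode ion, run is {polarity}"
            )
    theo = []
    for ai, a in enumerate(adducts):
        shift = ADDUCT_SHIFTS[a][0]
        for ri, rec in enumerate(records):
            theo.append((rec.monoisotopic_mass + shift, ri, ai))
    theo.sort(key=lambda t: t[0])
    theo_mz = np.array([t[0] for t in theo])

    hits: list[AnnotationHit] = []
    tol = tol_ppm * 1e-6
    for fmz in np.asarray(features, dtype=float):
        lo = np.searchsorted(theo_mz, fmz / (1 + tol), side="left")
        hi = np.searchsorted(theo_mz, fmz / (1 - tol), side="right")
        feature_hits = []
        for k in range(lo, hi):
            tmz, ri, ai = theo[k]
            ppm = (fmz - tmz) / tmz * 1e6
            if abs(ppm) <= tol_ppm:
                rec = records[ri]
                feature_hits.append(
                    AnnotationHit(
                        feature_mz=float(fmz),
                        record_id=rec.record_id,
                        name=rec.name,
                        adduct=adducts[ai],
                        theoretical_mz=float(tmz),
                        ppm_error=float(ppm),
                    )
                )
        feature_hits.sort(key=lambda h: (abs(h.ppm_error), h.record_id, h.adduct))
        hits.extend(feature_hits)
    return hits


def hits_to_frame(hits: list[AnnotationHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "feature_mz": h.feature_mz,
                "record_id": h.record_id,
                "name": h.name,
                "adduct": h.adduct,
                "theoretical_mz": h.theoretical_mz,
                "ppm_error": h.ppm_error,
            }
            for h in hits
        ],
        columns=["feature_mz", "record_id", "name", "adduct", "theoretical_mz", "ppm_error"],
    )
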