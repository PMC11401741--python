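"""Reading and writing scan-series data and result tables.

Supported interchange formats:

* **mzML** (PSI standard, centroided MS1): read by a namespace-aware
  lxml parser (32/64-bit float arrays, zlib or uncompressed, minute or
  second retention-time units, plain or indexed mzML), written by a
  minimal standard-conformant writer (64-bit float arrays, base64, no
  compression). Vendor RAW/WIFF files are not read natively — convert to
  mzML, or register a reader plugin for the extension.
* **Long CSV** dialect: header ``scan,rt_s,mz,intensity``, rows sorted by
  (scan, m/z); multiple files concatenate in argument order.
* Matrix CSV + cell-metadata sidecar, and a directory *bundle* holding
  every layer of an :class:`~scmpipe.model.SCData` as plain text.
"""

from __future__ import annotations

import base64
import json
import logging
import zlib
from pathlib import Path
from typing import Callable
from xml.sax.saxutils import escape

import numpy as np
import pandas as pd
from lxml import etree

from .errors import EmptyRunError, InvariantError
from .model import (
    CellEvent,
    CellMatrix,
    PeakTable,
    ScanSeries,
    SCData,
    Spectrum,
    concat_series,
)

logger = logging.getLogger(__name__)

LONG_CSV_HEADER = ["scan", "rt_s", "mz", "intensity"]

# extension -> reader(path) -> ScanSeries; vendor formats plug in here
READER_REGISTRY: dict[str, Callable[[str | Path], ScanSeries]] = {}


def register_reader(extension: str, reader: Callable[[str | Path], ScanSeries]) -> None:
    """Register a scan-series reader for a file extension (e.g. ``.raw``)."""
    READER_REGISTRY[extension.lower()] = reader


def read_any(path: str | Path) -> ScanSeries:
    """Dispatch to the reader registered for the file's extension."""
    ext = Path(path).suffix.lower()
    if ext == ".mzml":
        return read_mzml(path)
    if ext == ".csv":
        return read_long_csv([path])
    if ext in READER_REGISTRY:
        return READER_REGISTRY[ext](path)
    raise InvariantError(
        f"no reader for {ext!r} files; convert to mzML or register a plugin"
    )


# ---------------------------------------------------------------- mzML

_NS = "http://psi.hupo.org/ms/mzml"

# PSI-MS controlled-vocabulary accessions used by the parser
_CV_MS_LEVEL = "MS:1000511"
_CV_CENTROID = "MS:1000127"
_CV_PROFILE = "MS:1000128"
_CV_SCAN_START = "MS:1000016"
_CV_F64 = "MS:1000523"
_CV_F32 = "MS:1000521"
_CV_ZLIB = "MS:1000574"
_CV_MZ_ARRAY = "MS:1000514"
_CV_INT_ARRAY = "MS:1000515"
_CV_POS_SCAN = "MS:1000130"
_CV_NEG_SCAN = "MS:1000129"


def _decode_binary_array(bda: etree._Element) -> tuple[str | None, np.ndarray]:
    """Decode one <binaryDataArray>: returns (kind, values)."""
    dtype = "<f8"
    compressed = False
    kind = None
    for cv in bda.iter(f"{{{_NS}}}cvParam"):
        acc = cv.get("accession")
        if acc == _CV_F32:
            dtype = "<f4"
        elif acc == _CV_ZLIB:
            compressed = True
        elif acc == _CV_MZ_ARRAY:
            kind = "mz"
        elif acc == _CV_INT_ARRAY:
            kind = "intensity"
    binary = bda.find(f"{{{_NS}}}binary")
    text = (binary.text or "") if binary is not None else ""
    raw = base64.b64decode(text)
    if compressed:
        raw = zlib.decompress(raw)
    return kind, np.frombuffer(raw, dtype=dtype).astype(np.float64)


def read_mzml(path: str | Path) -> ScanSeries:
    """Read centroided MS1 scans from an mzML (or indexedmzML) file.

    MS2+ scans are skipped (counted in the log); retention times are
    normalized to seconds; profile-mode spectra are rejected — centroid
    first, the pipeline is defined on centroids.
    """
    spectra: list[Spectrum] = []
    skipped = 0
    polarity = "unknown"
    try:
        context = etree.iterparse(
            str(path), events=("end",), tag=f"{{{_NS}}}spectrum"
        )
        for _, elem in context:
            ms_level = None
            profile = False
            for cv in elem.findall(f"{{{_NS}}}cvParam"):
                acc = cv.get("accession")
                if acc == _CV_MS_LEVEL:
                    ms_level = int(cv.get("value"))
                elif acc == _CV_PROFILE:
                    profile = True
                elif acc == _CV_POS_SCAN:
                    polarity = "positive"
                elif acc == _CV_NEG_SCAN:
                    polarity = "negative"
            if ms_level != 1:
                skipped += 1
                elem.clear()
                continue
            if profile:
                raise InvariantError(
                    f"{path}: spectrum {elem.get('id')} is profile mode; "
                    "centroid the data first (e.g. msconvert --filter "
                    "'peakPicking')"
                )
            rt_s = 0.0
            for cv in elem.iter(f"{{{_NS}}}cvParam"):
                if cv.get("accession") == _CV_SCAN_START:
                    rt_s = float(cv.get("value"))
                    if "minute" in (cv.get("unitName") or ""):
                        rt_s *= 60.0
                    break
            mz = np.array([], dtype=float)
            inten = np.array([], dtype=float)
            for bda in elem.iter(f"{{{_NS}}}binaryDataArray"):
                kind, values = _decode_binary_array(bda)
                if kind == "mz":
                    mz = values
                elif kind == "intensity":
                    inten = values
            order = np.argsort(mz, kind="stable")
            spectra.append(Spectrum(len(spectra), rt_s, mz[order], inten[order]))
            elem.clear()
    except etree.XMLSyntaxError as exc:
        raise InvariantError(f"{path}: malformed mzML ({exc})") from exc
    if skipped:
        logger.info("%s: skipped %d non-MS1 scans", path, skipped)
    if not spectra:
        raise EmptyRunError(f"{path}: no MS1 scans found")
    return ScanSeries(spectra, source_files=[str(path)], polarity=polarity)


def _b64_doubles(values: np.ndarray) -> str:
    raw = np.asarray(values, dtype="<f8").tobytes()
    return base64.b64encode(raw).decode("ascii")


_MZML_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0" id="{run_id}">
  <cvList count="2">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
    <cv id="UO" fullName="Unit Ontology" URI="https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo"/>
  </cvList>
  <fileDescription>
    <fileContent>
      <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>
      <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
    </fileContent>
  </fileDescription>
  <softwareList count="1">
    <software id="scmpipe" version="0.1.0">
      <cvParam cvRef="MS" accession="MS:1000799" name="custom unreleased software tool" value="scmpipe"/>
    </software>
  </softwareList>
  <instrumentConfigurationList count="1">
    <instrumentConfiguration id="IC1">
      <cvParam cvRef="MS" accession="MS:1000031" name="instrument model" value=""/>
    </instrumentConfiguration>
  </instrumentConfigurationList>
  <dataProcessingList count="1">
    <dataProcessing id="DP1">
      <processingMethod order="1" softwareRef="scmpipe">
        <cvParam cvRef="MS" accession="MS:1000544" name="Conversion to mzML" value=""/>
      </processingMethod>
    </dataProcessing>
  </dataProcessingList>
  <run id="{run_id}" defaultInstrumentConfigurationRef="IC1">
    <spectrumList count="{n}" defaultDataProcessingRef="DP1">
"""

_POLARITY_CV = {
    "positive": '<cvParam cvRef="MS" accession="MS:1000130" name="positive scan" value=""/>',
    "negative": '<cvParam cvRef="MS" accession="MS:1000129" name="negative scan" value=""/>',
}


def write_mzml(series: ScanSeries, path: str | Path) -> None:
    """Write a centroid MS1 mzML file readable by standard tools."""
    path = Path(path)
    parts = [_MZML_HEADER.format(run_id=escape("scmpipe_run"), n=series.n_scans)]
    for i, s in enumerate(series.spectra):
        mz_b64 = _b64_doubles(s.mz)
        int_b64 = _b64_doubles(s.intensity)
        polarity_cv = _POLARITY_CV.get(series.polarity, "")
        parts.append(
            f"""      <spectrum index="{i}" id="scan={s.scan_index + 1}" defaultArrayLength="{s.n_peaks}">
        <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>
        <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
        {polarity_cv}
        <scanList count="1">
          <cvParam cvRef="MS" accession="MS:1000795" name="no combination" value=""/>
          <scan>
            <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{s.retention_time!r}" unitCvRef="UO" unitAccession="UO:0000010" unitName="second"/>
          </scan>
        </scanList>
        <binaryDataArrayList count="2">
          <binaryDataArray encodedLength="{len(mz_b64)}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value="" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>
            <binary>{mz_b64}</binary>
          </binaryDataArray>
          <binaryDataArray encodedLength="{len(int_b64)}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value="" unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>
            <binary>{int_b64}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>
"""
        )
    parts.append("    </spectrumList>\n  </run>\n</mzML>\n")
    path.write_text("".join(parts), encoding="utf-8")


# ---------------------------------------------------------------- long CSV


def _read_one_long_csv(path: str | Path) -> ScanSeries:
    df = pd.read_csv(path)
    if list(df.columns) != LONG_CSV_HEADER:
        raise InvariantError(
            f"{path}: header must be exactly {','.join(LONG_CSV_HEADER)}, "
            f"got {','.join(map(str, df.columns))}"
        )
    spectra = []
    for scan, grp in df.groupby("scan", sort=True):
        rts = grp["rt_s"].unique()
        if rts.size != 1:
            raise InvariantError(f"{path}: scan {scan} has multiple retention times")
        grp = grp.sort_values("mz", kind="stable")
        spectra.append(
            Spectrum(
                int(scan),
                float(rts[0]),
                grp["mz"].to_numpy(dtype=float),
                grp["intensity"].to_numpy(dtype=float),
            )
        )
    series = ScanSeries(spectra, source_files=[str(path)])  # validates monotone rt
    return series


def read_long_csv(paths: list[str | Path]) -> ScanSeries:
    """Read one or more long-format CSV files as a single run.

    Files concatenate in argument order; scan indices are renumbered
    consecutively and retention times of later files are shifted so the
    combined series stays strictly increasing (inter-file gap = median
    inter-scan interval).
    """
    if not paths:
        raise InvariantError("no input files")
    return concat_series([_read_one_long_csv(p) for p in paths])


def write_long_csv(series: ScanSeries, path: str | Path) -> None:
    rows = []
    for s in series.spectra:
        for mz, inten in zip(s.mz, s.intensity):
            rows.append((s.scan_index, s.retention_time, mz, inten))
    pd.DataFrame(rows, columns=LONG_CSV_HEADER).to_csv(path, index=False)


# ---------------------------------------------------------------- matrices


def export_matrix_csv(
    matrix: CellMatrix, path: str | Path, orientation: str = "cells_rows"
) -> None:
    """Write the matrix as CSV plus a ``*_cellmeta.csv`` sidecar.

    ``cells_rows`` puts one cell per row with 4-decimal feature-m/z
    column labels; ``features_rows`` is the transpose.
    """
    if matrix.n_cells == 0 or matrix.n_features == 0:
        raise InvariantError("refusing to export an empty matrix")
    if orientation not in ("cells_rows", "features_rows"):
        raise InvariantError(f"unknown orientation {orientation!r}")
    path = Path(path)
    frame = matrix.to_frame()
    if orientation == "features_rows":
        frame = frame.T
        frame.index.name = "feature_mz"
    frame.to_csv(path)
    sidecar = path.with_name(path.stem + "_cellmeta.csv")
    matrix.cell_meta.to_csv(sidecar, index=False)


# ---------------------------------------------------------------- bundles


def save_bundle(scdata: SCData, directory: str | Path) -> None:
    """Serialize every populated layer of an SCData to a directory."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_long_csv(scdata.raw, d / "scans.csv")
    state = {
        "polarity": scdata.raw.polarity,
        "meta": scdata.raw.meta,
        "params": scdata.params,
    }
    if scdata.peaks is not None:
        scdata.peaks.rows.to_csv(d / "peaks.csv", index=False)
        scdata.peaks.bins.to_csv(d / "bins.csv")
        scdata.peaks.scan_rt.rename("rt_s").to_csv(d / "scan_rt.csv")
    if scdata.cells is not None:
        pd.DataFrame(
            [
                {
                    "cell_id": e.cell_id,
                    "apex_scan": e.apex_scan,
                    "start": e.start,
                    "end": e.end,
                    "apex_snr": e.apex_snr,
                    "noise_scans": ";".join(map(str, e.noise_scans)),
                }
                for e in scdata.cells
            ]
        ).to_csv(d / "cells.csv", index=False)
    if scdata.matrix is not None:
        export_matrix_csv(scdata.matrix, d / "matrix.csv")
        state["matrix_layer"] = scdata.matrix.layer
        state["matrix_log_base"] = scdata.matrix.log_base
        state["matrix_provenance"] = scdata.matrix.provenance
    (d / "params.json").write_text(json.dumps(state, indent=2, default=str))


def load_bundle(directory: str | Path) -> SCData:
    """Load a bundle written by :func:`save_bundle`.

    The raw layer and params log are always restored; derived layers are
    restored where present (the matrix comes back with its layer tag,
    sufficient for export and downstream analysis).
    """
    d = Path(directory)
    state = json.loads((d / "params.json").read_text())
    raw = read_long_csv([d / "scans.csv"])
    raw.polarity = state.get("polarity", "unknown")
    raw.meta = state.get("meta", {})
    scd = SCData(raw)
    scd.params = state.get("params", [])
    if (d / "peaks.csv").exists():
        rows = pd.read_csv(d / "peaks.csv")
        bins = pd.read_csv(d / "bins.csv", index_col="bin_id")
        scan_rt_df = pd.read_csv(d / "scan_rt.csv", index_col="scan_index")
        scd.peaks = PeakTable(rows, bins, scan_rt_df["rt_s"])
    if (d / "cells.csv").exists():
        cells_df = pd.read_csv(d / "cells.csv")
        scd.cells = [
            CellEvent(
                cell_id=int(r.cell_id),
                apex_scan=int(r.apex_scan),
                start=int(r.start),
                end=int(r.end),
                apex_snr=float(r.apex_snr),
                noise_scans=[int(x) for x in str(r.noise_scans).split(";") if x not in ("", "nan")],
            )
            for r in cells_df.itertuples()
        ]
    if (d / "matrix.csv").exists():
        frame = pd.read_csv(d / "matrix.csv", index_col="cell_id")
        meta = pd.read_csv(d / "matrix_cellmeta.csv")
        scd.matrix = CellMatrix(
            frame.to_numpy(dtype=float),
            np.array([float(c) for c in frame.columns]),
            [int(i) for i in frame.index],
            meta,
            layer=state.get("matrix_layer", "raw"),
            provenance=state.get("matrix_provenance", []),
            log_base=state.get("matrix_log_base"),
        )
    return scd
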