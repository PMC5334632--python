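"""Readers and writers for the pipeline's on-disk formats.

Runs are stored in a documented JSON schema (gzip-capable)::

    {"sample_id": ..., "metadata": {...},
     "spectra": [{"rt": float, "function": 1|2,
                  "mz": [...], "intensity": [...]}, ...]}

Feature tables are CSV with columns ``feature_id, mz, rt`` followed by
one column per sample; bioactivity tables are CSV with columns
``sample_id, viability_percent`` (a trailing ``%`` on the viability is
tolerated).  Centroided mzML is supported for import only, mapping MS
levels 1/2 onto the low/high collision-energy functions.
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .simulate import BioactivityRecord, FeatureTable, MseRun, Spectrum, TapRun

__all__ = [
    "MsDataError",
    "write_run", "read_run",
    "write_table", "read_table",
    "write_bioactivity", "read_bioactivity",
    "write_tap", "read_tap",
    "read_mzml",
]


class MsDataError(ValueError):
    """Raised for malformed pipeline files, naming the offending record."""


def _open(path: Path, mode: str):
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t")
    return open(path, mode)


def write_run(run: MseRun, path: str | Path) -> None:
    path = Path(path)
    payload = {
        "sample_id": run.sample_id,
        "metadata": run.metadata,
        "spectra": [
            {"rt": s.rt, "function": s.function,
             "mz": [float(v) for v in s.mz],
             "intensity": [float(v) for v in s.intensity]}
            for s in run.spectra
        ],
    }
    with _open(path, "w") as fh:
        json.dump(payload, fh)


def read_run(path: str | Path) -> MseRun:
    path = Path(path)
    with _open(path, "r") as fh:
        payload = json.load(fh)
    try:
        spectra = []
        for i, rec in enumerate(payload["spectra"]):
            try:
                spectra.append(Spectrum(
                    rt=float(rec["rt"]), function=int(rec["function"]),
                    mz=np.asarray(rec["mz"], dtype=float),
                    intensity=np.asarray(rec["intensity"], dtype=float),
                ))
            except (KeyError, ValueError, TypeError) as exc:
                raise MsDataError(f"{path}: malformed spectrum record {i}: {exc}") from exc
        return MseRun(sample_id=payload["sample_id"], spectra=spectra,
                      metadata=payload.get("metadata", {}))
    except KeyError as exc:
        raise MsDataError(f"{path}: missing field {exc}") from exc


def write_table(table: FeatureTable, path: str | Path) -> None:
    df = table.features.set_index("feature_id").join(table.matrix.T)
    df.to_csv(path, index_label="feature_id")


def read_table(path: str | Path) -> FeatureTable:
    df = pd.read_csv(path)
    required = {"feature_id", "mz", "rt"}
    if not required.issubset(df.columns):
        raise MsDataError(f"{path}: feature table must have columns {sorted(required)}")
    if df["feature_id"].duplicated().any():
        dup = df.loc[df["feature_id"].duplicated(), "feature_id"].iloc[0]
        raise MsDataError(f"{path}: duplicate feature_id {dup!r}")
    features = df[["feature_id", "mz", "rt"]].copy()
    sample_cols = [c for c in df.columns if c not in required]
    matrix = df.set_index("feature_id")[sample_cols].T
    matrix.columns = list(features["feature_id"])
    return FeatureTable(features, matrix.astype(float))


def write_bioactivity(records: Sequence[BioactivityRecord], path: str | Path) -> None:
    lines = ["sample_id,viability_percent"]
    lines += [f"{r.sample_id},{r.viability_percent}" for r in records]
    Path(path).write_text("\n".join(lines) + "\n")


def read_bioactivity(path: str | Path) -> list[BioactivityRecord]:
    path = Path(path)
    records = []
    with open(path) as fh:
        header = fh.readline().strip().split(",")
        if len(header) < 2:
            raise MsDataError(f"{path}: expected header 'sample_id,viability_percent'")
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = [p.strip() for p in line.split(",")]
            if len(parts) < 2 or not parts[1]:
                raise MsDataError(f"{path}: missing viability at line {lineno} ({line!r})")
            sid, raw = parts[0], parts[1].rstrip("%").strip()
            try:
                viability = float(raw)
            except ValueError as exc:
                raise MsDataError(
                    f"{path}: unparseable viability {parts[1]!r} at line {lineno}"
                ) from exc
            records.append(BioactivityRecord(sample_id=sid, viability_percent=viability))
    return records


def write_tap(tap: TapRun, path: str | Path) -> None:
    payload = {
        "precursor_mz": tap.precursor_mz,
        "primary_peaks": [[float(m), float(d), float(i)] for m, d, i in tap.primary_peaks],
        "secondary_spectra": [
            {"drift": float(d),
             "mz": [float(v) for v in s.mz],
             "intensity": [float(v) for v in s.intensity]}
            for d, s in tap.secondary_spectra
        ],
    }
    with _open(Path(path), "w") as fh:
        json.dump(payload, fh)


def read_tap(path: str | Path) -> TapRun:
    path = Path(path)
    with _open(path, "r") as fh:
        payload = json.load(fh)
    try:
        secondary = [
            (float(rec["drift"]),
             Spectrum(rt=0.0, function=2,
                      mz=np.asarray(rec["mz"], dtype=float),
                      intensity=np.asarray(rec["intensity"], dtype=float)))
            for rec in payload["secondary_spectra"]
        ]
        return TapRun(
            precursor_mz=float(payload["precursor_mz"]),
            primary_peaks=[tuple(p) for p in payload["primary_peaks"]],
            secondary_spectra=secondary,
        )
    except (KeyError, ValueError, TypeError) as exc:
        raise MsDataError(f"{path}: malformed TAP file: {exc}") from exc


# -- minimal mzML import ----------------------------------------------------
#
# Only the subset needed for centroided MS^E data is read: per-spectrum
# ms level, scan start time, and the m/z / intensity binary arrays
# (32/64-bit float, plain or zlib-compressed base64).

_MZML_NS = "{http://psi.hupo.org/ms/mzml}"
_ACC_MS_LEVEL = "MS:1000511"
_ACC_SCAN_TIME = "MS:1000016"
_ACC_F64 = "MS:1000523"
_ACC_F32 = "MS:1000521"
_ACC_ZLIB = "MS:1000574"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INT_ARRAY = "MS:1000515"


def _decode_binary_array(elem) -> tuple[str | None, np.ndarray]:
    import base64
    import struct
    import zlib

    accessions = {cv.get("accession") for cv in elem.iter(f"{_MZML_NS}cvParam")}
    kind = ("mz" if _ACC_MZ_ARRAY in accessions
            else "intensity" if _ACC_INT_ARRAY in accessions else None)
    binary = elem.find(f"{_MZML_NS}binary")
    raw = base64.b64decode((binary.text or "").strip()) if binary is not None else b""
    if _ACC_ZLIB in accessions:
        raw = zlib.decompress(raw)
    width, code = (4, "f") if _ACC_F32 in accessions else (8, "d")
    values = struct.unpack(f"<{len(raw) // width}{code}", raw)
    return kind, np.asarray(values, dtype=float)


def read_mzml(path: str | Path, sample_id: str | None = None) -> MseRun:
    """Import a centroided mzML file as a two-function MS^E run.

    MS level 1 scans map to function 1 (low collision energy) and MS
    level 2 scans to function 2.  Retention times are converted to
    minutes when the file reports them in seconds.
    """
    import xml.etree.ElementTree as ET

    path = Path(path)
    spectra = []
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise MsDataError(f"{path}: not a valid mzML/XML file: {exc}") from exc
    for i, spec_elem in enumerate(root.iter(f"{_MZML_NS}spectrum")):
        try:
            level, rt_min = 1, 0.0
            for cv in spec_elem.iter(f"{_MZML_NS}cvParam"):
                acc = cv.get("accession")
                if acc == _ACC_MS_LEVEL:
                    level = int(cv.get("value"))
                elif acc == _ACC_SCAN_TIME:
                    rt_min = float(cv.get("value"))
                    if cv.get("unitName", "minute").startswith("second"):
                        rt_min /= 60.0
            arrays: dict[str, np.ndarray] = {}
            for arr_elem in spec_elem.iter(f"{_MZML_NS}binaryDataArray"):
                kind, values = _decode_binary_array(arr_elem)
                if kind:
                    arrays[kind] = values
            spectra.append(Spectrum(
                rt=rt_min, function=1 if level == 1 else 2,
                mz=arrays.get("mz", np.array([])),
                intensity=arrays.get("intensity", np.array([])),
            ))
        except (KeyError, ValueError, TypeError) as exc:
            raise MsDataError(f"{path}: malformed mzML spectrum {i}: {exc}") from exc
    return MseRun(sample_id=sample_id or path.stem, spectra=spectra,
                  metadata={"source": str(path), "format": "mzML"})
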