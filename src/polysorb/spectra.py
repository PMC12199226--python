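"""Data model and I/O for centroided MS runs organised as DIA cycles.

A LESA run on one polymer spot is a direct-infusion acquisition: repeated
cycles of ``cycle_length`` targeted MS2 scans (each isolating one peptide
ion in a narrow window, 1 m/z by default) followed by a single MS1 survey
scan over m/z 400–900.  Retention time carries no information and is kept
only as optional metadata.

The canonical on-disk format is a "run table" CSV (one row per scan, peak
arrays semicolon-joined) because MGF cannot represent MS1 scans.  MGF export
of the MS2 scans and mzML import are provided as interop conveniences via
pyteomics.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import base64
import zlib

import numpy as np
from lxml import etree
from pyteomics import mgf as _pt_mgf

__all__ = [
    "Spectrum",
    "Run",
    "Cycle",
    "AcquisitionScheme",
    "read_run",
    "write_run",
    "write_mgf",
    "read_mzml",
    "cycles",
]


@dataclass
class Spectrum:
    """A centroided scan: parallel m/z (ascending) and intensity arrays."""

    scan_id: int
    ms_level: int
    mz: np.ndarray
    intensity: np.ndarray
    precursor_mz: float | None = None  # MS2 only
    isolation_width: float | None = None  # MS2 only
    scan_range: tuple[float, float] | None = None  # MS1 only
    retention_time: float | None = None

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError(f"scan {self.scan_id}: mz/intensity length mismatch")
        if self.mz.size and np.any(np.diff(self.mz) <= 0):
            order = np.argsort(self.mz, kind="stable")
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]
            if np.any(np.diff(self.mz) <= 0):
                raise ValueError(
                    f"scan {self.scan_id}: duplicate m/z values after sorting"
                )
        if np.any(self.intensity < 0):
            raise ValueError(f"scan {self.scan_id}: negative intensity")
        if self.ms_level not in (1, 2):
            raise ValueError(f"scan {self.scan_id}: ms_level must be 1 or 2")
        if self.ms_level == 2 and self.precursor_mz is None:
            raise ValueError(f"scan {self.scan_id}: MS2 scan lacks precursor_mz")
        if self.ms_level == 1 and self.scan_range is None:
            raise ValueError(f"scan {self.scan_id}: MS1 scan lacks scan_range")

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)


@dataclass
class Run:
    """An ordered sequence of scans from one polymer spot × replicate."""

    run_id: str
    spectra: list[Spectrum]
    cycle_length: int = 10

    def __post_init__(self) -> None:
        ids = [s.scan_id for s in self.spectra]
        if ids != sorted(ids):
            raise ValueError("spectra must be ordered by scan_id")

    def ms1_scans(self) -> list[Spectrum]:
        return [s for s in self.spectra if s.ms_level == 1]

    def ms2_scans(self) -> list[Spectrum]:
        return [s for s in self.spectra if s.ms_level == 2]


@dataclass
class Cycle:
    """One DIA cycle: the MS2 scans acquired before (and with) one MS1 scan."""

    ms2: list[Spectrum]
    ms1: Spectrum | None
    complete: bool


@dataclass
class AcquisitionScheme:
    """Targeted-DIA scheme: which peptide ions the MS2 scans cycle through."""

    targets: list[tuple[str, int, float]]  # (peptide_id, charge, precursor_mz)
    isolation_width: float = 1.0
    ms1_range: tuple[float, float] = (400.0, 900.0)
    cycle_length: int = 10

    def __post_init__(self) -> None:
        if self.isolation_width <= 0:
            raise ValueError("isolation_width must be > 0")


def cycles(run: Run) -> list[Cycle]:
    """Partition a run into DIA cycles (cycle_length MS2 then one MS1).

    An MS1 appearing before ``cycle_length`` MS2 scans have accumulated
    closes the cycle early with a structural warning; a trailing group with
    no MS1 is retained flagged incomplete.
    """
    out: list[Cycle] = []
    pending: list[Spectrum] = []
    for spec in run.spectra:
        if spec.ms_level == 2:
            pending.append(spec)
            continue
        if len(pending) < run.cycle_length:
            warnings.warn(
                f"run {run.run_id}: MS1 scan {spec.scan_id} after only "
                f"{len(pending)} MS2 scans; splitting cycle early",
                stacklevel=2,
            )
        out.append(Cycle(ms2=pending, ms1=spec, complete=len(pending) == run.cycle_length))
        pending = []
    if pending:
        out.append(Cycle(ms2=pending, ms1=None, complete=False))
    return out


# ---------------------------------------------------------------------------
# Run-table CSV

_COLUMNS = [
    "scan_id",
    "ms_level",
    "retention_time",
    "precursor_mz",
    "isolation_width",
    "scan_low",
    "scan_high",
    "mz_array",
    "intensity_array",
]


def _fmt(x: float | None) -> str:
    return "" if x is None else format(x, ".17g")


def _join(arr: np.ndarray) -> str:
    return ";".join(format(v, ".17g") for v in arr)


def _split(text: str) -> np.ndarray:
    if not text:
        return np.array([], dtype=float)
    return np.array([float(t) for t in text.split(";")], dtype=float)


def write_run(run: Run, path: str | Path) -> None:
    """Write a run table CSV: header line with run metadata, then one row per scan."""
    lines = [f"#run_id={run.run_id},cycle_length={run.cycle_length}"]
    lines.append(",".join(_COLUMNS))
    for s in run.spectra:
        low, high = s.scan_range if s.scan_range is not None else (None, None)
        lines.append(
            ",".join(
                [
                    str(s.scan_id),
                    str(s.ms_level),
                    _fmt(s.retention_time),
                    _fmt(s.precursor_mz),
                    _fmt(s.isolation_width),
                    _fmt(low),
                    _fmt(high),
                    _join(s.mz),
                    _join(s.intensity),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_run(path: str | Path) -> Run:
    """Read a run table CSV (or an mzML file, dispatched on extension)."""
    path = Path(path)
    if path.suffix.lower() == ".mzml":
        return read_mzml(path)
    text = path.read_text().splitlines()
    if not text or not text[0].startswith("#run_id="):
        raise ValueError(f"{path}: not a run table (missing #run_id header)")
    meta = dict(kv.split("=", 1) for kv in text[0][1:].split(","))
    run_id = meta["run_id"]
    cycle_length = int(meta.get("cycle_length", 10))
    if len(text) < 2 or text[1].split(",")[: len(_COLUMNS)] != _COLUMNS:
        raise ValueError(f"{path}: malformed run-table column header")
    spectra: list[Spectrum] = []
    for lineno, line in enumerate(text[2:], start=3):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) != len(_COLUMNS):
            raise ValueError(f"{path}:{lineno}: expected {len(_COLUMNS)} fields")
        scan_id = int(parts[0])
        try:
            spectra.append(
                Spectrum(
                    scan_id=scan_id,
                    ms_level=int(parts[1]),
                    retention_time=float(parts[2]) if parts[2] else None,
                    precursor_mz=float(parts[3]) if parts[3] else None,
                    isolation_width=float(parts[4]) if parts[4] else None,
                    scan_range=(float(parts[5]), float(parts[6]))
                    if parts[5] and parts[6]
                    else None,
                    mz=_split(parts[7]),
                    intensity=_split(parts[8]),
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}: scan_id {scan_id}: {exc}") from exc
    return Run(run_id=run_id, spectra=spectra, cycle_length=cycle_length)


# ---------------------------------------------------------------------------
# MGF export (MS2 only) and mzML import via pyteomics

def write_mgf(run: Run, path: str | Path) -> int:
    """Export the MS2 scans as MGF; returns the number of blocks written.

    MGF has no MS1 concept, so survey scans are dropped on export.
    """
    entries = []
    for s in run.ms2_scans():
        params = {
            "title": f"{run.run_id}.{s.scan_id}",
            "pepmass": (s.precursor_mz,),
        }
        entries.append(
            {"params": params, "m/z array": s.mz, "intensity array": s.intensity}
        )
    _pt_mgf.write(entries, str(path), file_mode="w")
    return len(entries)


_MZML_NS = "{http://psi.hupo.org/ms/mzml}"


def _cv_params(element) -> dict[str, str]:
    return {
        cv.get("name"): cv.get("value", "")
        for cv in element.iter(_MZML_NS + "cvParam")
    }


def _decode_binary_array(array_element) -> tuple[str | None, np.ndarray]:
    """Decode one <binaryDataArray>: returns (array name, float array)."""
    params = _cv_params(array_element)
    binary = array_element.find(_MZML_NS + "binary")
    raw = base64.b64decode(binary.text or "")
    if "zlib compression" in params:
        raw = zlib.decompress(raw)
    dtype = "<f4" if "32-bit float" in params else "<f8"
    values = np.frombuffer(raw, dtype=dtype).astype(float)
    name = next((n for n in ("m/z array", "intensity array") if n in params), None)
    return name, values


def read_mzml(path: str | Path, cycle_length: int = 10) -> Run:
    """Read a centroided mzML file into a Run.

    Compact reader for the subset of mzML this pipeline consumes: ms level,
    precursor selected-ion m/z and isolation offsets, scan windows, and
    32/64-bit (optionally zlib-compressed) peak arrays.
    """
    tree = etree.parse(str(path))
    spectra: list[Spectrum] = []
    for i, spec in enumerate(tree.iter(_MZML_NS + "spectrum")):
        top = _cv_params(spec)
        level = int(top.get("ms level", "1"))
        precursor = None
        width = None
        scan_range = None
        if level == 2:
            sel = spec.find(f".//{_MZML_NS}selectedIon")
            if sel is None:
                raise ValueError(f"{path}: MS2 spectrum {i} lacks a selected ion")
            precursor = float(_cv_params(sel)["selected ion m/z"])
            iso = spec.find(f".//{_MZML_NS}isolationWindow")
            if iso is not None:
                iso_params = _cv_params(iso)
                lo = iso_params.get("isolation window lower offset")
                hi = iso_params.get("isolation window upper offset")
                if lo is not None and hi is not None:
                    width = float(lo) + float(hi)
        mz = np.array([])
        intensity = np.array([])
        for array_element in spec.iter(_MZML_NS + "binaryDataArray"):
            name, values = _decode_binary_array(array_element)
            if name == "m/z array":
                mz = values
            elif name == "intensity array":
                intensity = values
        if level == 1:
            window = spec.find(f".//{_MZML_NS}scanWindow")
            if window is not None:
                wp = _cv_params(window)
                scan_range = (
                    float(wp["scan window lower limit"]),
                    float(wp["scan window upper limit"]),
                )
            else:
                scan_range = (
                    float(mz.min(initial=0.0)),
                    float(mz.max(initial=0.0)),
                )
        spectra.append(
            Spectrum(
                scan_id=i + 1,
                ms_level=level,
                mz=mz,
                intensity=intensity,
                precursor_mz=precursor,
                isolation_width=width,
                scan_range=scan_range,
            )
        )
    return Run(run_id=Path(path).stem, spectra=spectra, cycle_length=cycle_length)
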