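"""Spectral library and cosine-correlation identification of targeted DIA scans.

Identification follows the library-matching rule used throughout the
pipeline: a query MS2 scan is accepted for a peptide ion when its cosine
similarity to the library spectrum exceeds 0.95 (strict) AND at least five
fragment peaks pair within the fragment tolerance (0.02 Da by default).

The cosine is computed over the *union* vector: query and library peaks are
paired greedily by ascending m/z distance (each peak used at most once, a
pair admitted iff |Δm/z| <= tolerance); paired peaks contribute to the
cross term, unmatched peaks of either side contribute only to their own
norm.  This is the conservative reading of "cosine correlation" — unmatched
signal penalises the score, which keeps a 0.95 threshold meaningful.
Matched-only vectorisation and square-root/log intensity weighting are
available as options.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np

from .digest import MassTable, DEFAULT_MASS_TABLE, Peptide, fragment_ions, precursor_mz
from .spectra import AcquisitionScheme, Run, Spectrum

__all__ = [
    "SpectralLibraryEntry",
    "MatchResult",
    "build_library_from_truth",
    "import_library",
    "export_library",
    "read_msp",
    "match_spectrum",
    "greedy_pair",
    "accept",
    "identify_run",
]

DEFAULT_FRAG_TOL = 0.02  # Da
DEFAULT_COS_MIN = 0.95
DEFAULT_MIN_FRAG = 5


@dataclass
class SpectralLibraryEntry:
    """Reference fragment spectrum for one peptide ion."""

    peptide_id: str
    protein_id: str
    sequence: str
    charge: int
    precursor_mz: float
    fragment_mz: np.ndarray
    fragment_intensity: np.ndarray
    provenance: str = "ground-truth"

    def __post_init__(self) -> None:
        self.fragment_mz = np.asarray(self.fragment_mz, dtype=float)
        self.fragment_intensity = np.asarray(self.fragment_intensity, dtype=float)
        if self.fragment_mz.size == 0:
            raise ValueError(f"library entry {self.peptide_id}/{self.charge}: no fragments")
        order = np.argsort(self.fragment_mz, kind="stable")
        self.fragment_mz = self.fragment_mz[order]
        self.fragment_intensity = self.fragment_intensity[order]

    @property
    def key(self) -> tuple[str, int]:
        return (self.peptide_id, self.charge)


@dataclass
class MatchResult:
    query_scan: int
    peptide_id: str | None
    charge: int | None
    cosine: float
    n_matched: int
    accepted: bool


def uniform_intensity_model(peptide: Peptide, series: str, index: int, charge: int) -> float:
    """Flat fragment intensities (default library realisation)."""
    return 100.0


def triangular_intensity_model(peptide: Peptide, series: str, index: int, charge: int) -> float:
    """Deterministic non-flat model: mid-sequence fragments strongest."""
    n = len(peptide.sequence)
    return 50.0 + 100.0 * (index * (n - index)) / (n * n / 4.0)


def build_library_from_truth(
    peptides: Sequence[Peptide],
    charges: Iterable[int],
    intensity_model: Callable[[Peptide, str, int, int], float] = uniform_intensity_model,
    fragment_max_charge: int = 1,
    table: MassTable = DEFAULT_MASS_TABLE,
) -> list[SpectralLibraryEntry]:
    """One entry per (peptide, precursor charge) with b/y fragments from sequence.

    Stands in for a search-engine-built library when simulating: fragment m/z
    come from the residue masses, intensities from a deterministic model.
    """
    charges = list(charges)
    entries: list[SpectralLibraryEntry] = []
    for pep in peptides:
        if len(pep.sequence) < 2:
            import warnings

            warnings.warn(f"skipping peptide {pep.sequence!r}: too short to fragment")
            continue
        ions = fragment_ions(pep, max_charge=fragment_max_charge, table=table)
        mz = np.array([ion.mz for ion in ions])
        inten = np.array(
            [intensity_model(pep, ion.series, ion.index, ion.charge) for ion in ions]
        )
        for z in charges:
            entries.append(
                SpectralLibraryEntry(
                    peptide_id=pep.sequence,
                    protein_id=pep.protein_id,
                    sequence=pep.sequence,
                    charge=z,
                    precursor_mz=precursor_mz(pep.monoisotopic_mass, z, table),
                    fragment_mz=mz.copy(),
                    fragment_intensity=inten.copy(),
                    provenance="ground-truth",
                )
            )
    return entries


# ---------------------------------------------------------------------------
# Peak pairing + cosine

def greedy_pair(
    mz_a: np.ndarray, mz_b: np.ndarray, tol: float
) -> list[tuple[int, int]]:
    """Pair peaks one-to-one, greedily by ascending |Δm/z|, within tol.

    Deterministic: candidate pairs sorted by (|Δ|, index_a, index_b).  On the
    sparse spectra of tryptic peptides at 0.02 Da this equals the pairing
    that maximises the number of matches (verified against an exhaustive
    oracle in the tests).
    """
    candidates: list[tuple[float, int, int]] = []
    j0 = 0
    for i, ma in enumerate(mz_a):
        for j in range(len(mz_b)):
            d = abs(ma - mz_b[j])
            if d <= tol:
                candidates.append((d, i, j))
    candidates.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for _, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((i, j))
    return pairs


def _transform(x: np.ndarray, weighting: str) -> np.ndarray:
    if weighting == "raw":
        return x
    if weighting == "sqrt":
        return np.sqrt(x)
    if weighting == "log":
        return np.log1p(x)
    raise ValueError(f"unknown intensity weighting {weighting!r}")


def match_spectrum(
    query: Spectrum,
    entry: SpectralLibraryEntry,
    frag_tol: float = DEFAULT_FRAG_TOL,
    cos_min: float = DEFAULT_COS_MIN,
    min_frag: int = DEFAULT_MIN_FRAG,
    vectorization: str = "union",
    weighting: str = "raw",
) -> MatchResult:
    """Score one MS2 scan against one library entry.

    union vectorisation: cosine = Σ q_i·l_i / (‖q‖·‖l‖) where the sums run
    over paired peaks for the cross term and over *all* peaks of each side
    for the norms.  matched vectorisation restricts the norms to paired
    peaks.
    """
    if frag_tol <= 0:
        raise ValueError("frag_tol must be > 0")
    if query.n_peaks == 0 or entry.fragment_mz.size == 0:
        return MatchResult(query.scan_id, entry.peptide_id, entry.charge, 0.0, 0, False)
    q = _transform(query.intensity, weighting)
    l = _transform(entry.fragment_intensity, weighting)
    pairs = greedy_pair(query.mz, entry.fragment_mz, frag_tol)
    cross = sum(q[i] * l[j] for i, j in pairs)
    if vectorization == "union":
        nq = math.sqrt(float(np.dot(q, q)))
        nl = math.sqrt(float(np.dot(l, l)))
    elif vectorization == "matched":
        nq = math.sqrt(sum(q[i] ** 2 for i, _ in pairs))
        nl = math.sqrt(sum(l[j] ** 2 for _, j in pairs))
    else:
        raise ValueError(f"unknown vectorization {vectorization!r}")
    cosine = cross / (nq * nl) if nq > 0 and nl > 0 else 0.0
    cosine = min(cosine, 1.0)  # guard rounding just above 1
    n_matched = len(pairs)
    return MatchResult(
        query_scan=query.scan_id,
        peptide_id=entry.peptide_id,
        charge=entry.charge,
        cosine=cosine,
        n_matched=n_matched,
        accepted=accept(cosine, n_matched, cos_min, min_frag),
    )


def accept(
    cosine: float,
    n_matched: int,
    cos_min: float = DEFAULT_COS_MIN,
    min_frag: int = DEFAULT_MIN_FRAG,
) -> bool:
    """Acceptance rule: cosine strictly above cos_min AND >= min_frag pairs."""
    return cosine > cos_min and n_matched >= min_frag


def identify_run(
    run: Run,
    library: Sequence[SpectralLibraryEntry],
    scheme: AcquisitionScheme | None = None,
    frag_tol: float = DEFAULT_FRAG_TOL,
    cos_min: float = DEFAULT_COS_MIN,
    min_frag: int = DEFAULT_MIN_FRAG,
    vectorization: str = "union",
    weighting: str = "raw",
) -> list[MatchResult]:
    """Identify every MS2 scan of a run against the in-window library entries.

    A library entry is a candidate for a scan iff its precursor m/z lies in
    the half-open isolation window [precursor − w/2, precursor + w/2).  The
    per-scan winner is the highest-cosine accepted entry (ties: more matched
    fragments, then lexicographic peptide id); if nothing is accepted the
    best-scoring candidate is reported unaccepted, and a scan with no
    in-window entry yields an unmatched result.
    """
    default_width = scheme.isolation_width if scheme is not None else 1.0
    results: list[MatchResult] = []
    for scan in run.ms2_scans():
        width = scan.isolation_width or default_width
        lo = scan.precursor_mz - width / 2.0
        hi = scan.precursor_mz + width / 2.0
        candidates = [e for e in library if lo <= e.precursor_mz < hi]
        if not candidates:
            results.append(MatchResult(scan.scan_id, None, None, 0.0, 0, False))
            continue
        matches = [
            match_spectrum(scan, e, frag_tol, cos_min, min_frag, vectorization, weighting)
            for e in candidates
        ]
        key = lambda m: (m.cosine, m.n_matched, _rev_lex(m.peptide_id))
        accepted = [m for m in matches if m.accepted]
        best = max(accepted, key=key) if accepted else max(matches, key=key)
        results.append(best)
    return results


class _rev_lex(str):
    """Orders strings reverse-lexicographically so max() prefers the smaller id."""

    def __lt__(self, other: str) -> bool:  # type: ignore[override]
        return str.__gt__(self, other)


# ---------------------------------------------------------------------------
# Library I/O: CSV and MSP-style text

_LIB_COLUMNS = [
    "peptide_id",
    "protein_id",
    "sequence",
    "charge",
    "precursor_mz",
    "fragment_mz",
    "fragment_intensity",
]


def export_library(entries: Sequence[SpectralLibraryEntry], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_LIB_COLUMNS)
        for e in entries:
            writer.writerow(
                [
                    e.peptide_id,
                    e.protein_id,
                    e.sequence,
                    e.charge,
                    format(e.precursor_mz, ".17g"),
                    ";".join(format(v, ".17g") for v in e.fragment_mz),
                    ";".join(format(v, ".17g") for v in e.fragment_intensity),
                ]
            )


def import_library(path: str | Path) -> list[SpectralLibraryEntry]:
    """Read a library CSV (or MSP-style text, dispatched on extension)."""
    path = Path(path)
    if path.suffix.lower() == ".msp":
        return read_msp(path)
    entries: list[SpectralLibraryEntry] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for i, row in enumerate(reader, start=2):
            mz = [float(v) for v in row["fragment_mz"].split(";") if v]
            inten = [float(v) for v in row["fragment_intensity"].split(";") if v]
            if not mz:
                raise ValueError(f"{path}:{i}: library entry has no peaks")
            entries.append(
                SpectralLibraryEntry(
                    peptide_id=row["peptide_id"],
                    protein_id=row["protein_id"],
                    sequence=row["sequence"],
                    charge=int(row["charge"]),
                    precursor_mz=float(row["precursor_mz"]),
                    fragment_mz=np.array(mz),
                    fragment_intensity=np.array(inten),
                    provenance="imported",
                )
            )
    return entries


def read_msp(path: str | Path) -> list[SpectralLibraryEntry]:
    """Parse an MSP-style library: Name / PrecursorMZ / Num peaks blocks."""
    entries: list[SpectralLibraryEntry] = []
    name = None
    precursor = None
    charge = 1
    protein = ""
    peaks: list[tuple[float, float]] = []
    expecting = 0

    def flush(lineno: int) -> None:
        nonlocal name, precursor, peaks
        if name is None:
            return
        if not peaks:
            raise ValueError(f"{path}:{lineno}: entry {name!r} has no peaks")
        mz, inten = zip(*peaks)
        seq = name.split("/")[0]
        entries.append(
            SpectralLibraryEntry(
                peptide_id=seq,
                protein_id=protein,
                sequence=seq,
                charge=charge,
                precursor_mz=float(precursor),
                fragment_mz=np.array(mz),
                fragment_intensity=np.array(inten),
                provenance="imported",
            )
        )
        name, precursor, peaks = None, None, []

    lineno = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                flush(lineno)
                continue
            low = line.lower()
            if low.startswith("name:"):
                flush(lineno)
                name = line.split(":", 1)[1].strip()
                charge = int(name.split("/")[1]) if "/" in name else 1
            elif low.startswith("precursormz:"):
                precursor = float(line.split(":", 1)[1])
            elif low.startswith("protein:"):
                protein = line.split(":", 1)[1].strip()
            elif low.startswith("num peaks:"):
                expecting = int(line.split(":", 1)[1])
            elif low.startswith("comment:"):
                continue
            else:
                parts = line.replace("\t", " ").split()
                if len(parts) < 2:
                    raise ValueError(f"{path}:{lineno}: malformed peak line {line!r}")
                try:
                    peaks.append((float(parts[0]), float(parts[1])))
                except ValueError as exc:
                    raise ValueError(
                        f"{path}:{lineno}: malformed peak line {line!r}"
                    ) from exc
        flush(lineno)
    return entries
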