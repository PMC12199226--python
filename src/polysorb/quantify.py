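"""MS1 label-free quantification, replicate aggregation and SNR filtering.

Relative protein adsorption is measured as the log10 of the summed MS1
intensities of a protein's accepted peptide ions in one run.  Missing
peptide intensities are imputed at the peak-intensity threshold (1000
counts) *before* summation and log transform, so every replicate value is
positive and the geometric mean across the (triplicate) polymer spots is
defined.  Polymers whose replicates disagree strongly — replicate SNR
(mean / sample sd of the linear-scale intensities) at or below 1.5 — are
removed before modelling, so the model sees adsorption behaviour rather
than measurement noise.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gmean

from .library import MatchResult
from .spectra import Run

__all__ = [
    "MISSING",
    "extract_ms1_intensity",
    "protein_log_intensity",
    "impute_missing",
    "geometric_mean",
    "replicate_snr",
    "coefficient_of_variation",
    "quantify_run",
    "build_adsorption_table",
    "snr_filter",
]

MISSING = float("nan")
DEFAULT_PPM_TOL = 10.0
DEFAULT_IMPUTE = 1000.0
DEFAULT_SNR_THRESHOLD = 1.5


def is_missing(value: float) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value))


def extract_ms1_intensity(
    run: Run, target_mz: float, ppm_tol: float = DEFAULT_PPM_TOL
) -> float:
    """Median across MS1 scans of the summed intensity within ±ppm_tol.

    Per MS1 scan the intensities of peaks with |mz − target|/target·1e6 <=
    ppm_tol are summed; scans with no in-window peak are ignored; the median
    of the remaining per-scan sums is returned (robust to single-scan spray
    instability).  MISSING (NaN) if no scan contains an in-window peak.
    """
    if ppm_tol <= 0:
        raise ValueError("ppm_tol must be > 0")
    ms1 = run.ms1_scans()
    if not ms1:
        warnings.warn(f"run {run.run_id}: no MS1 scans", stacklevel=2)
        return MISSING
    half_window = target_mz * ppm_tol * 1e-6
    sums = []
    for scan in ms1:
        lo = np.searchsorted(scan.mz, target_mz - half_window, side="left")
        hi = np.searchsorted(scan.mz, target_mz + half_window, side="right")
        if hi > lo:
            sums.append(float(scan.intensity[lo:hi].sum()))
    if not sums:
        return MISSING
    return float(np.median(sums))


def impute_missing(value: float, threshold: float = DEFAULT_IMPUTE) -> float:
    """Replace a missing peptide intensity with the peak-intensity threshold."""
    return threshold if is_missing(value) else value


def protein_log_intensity(intensities: Iterable[float]) -> float:
    """log10 of the summed present peptide intensities; MISSING if none present."""
    present = [v for v in intensities if not is_missing(v)]
    if not present:
        return MISSING
    total = float(sum(present))
    if total <= 0:
        return MISSING
    return math.log10(total)


def geometric_mean(values: Sequence[float]) -> float:
    """exp(mean(log values)); requires strictly positive inputs."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("geometric mean of an empty sequence")
    if np.any(arr <= 0) or np.any(np.isnan(arr)):
        raise ValueError("geometric mean requires strictly positive values")
    return float(gmean(arr))


def replicate_snr(
    values: Sequence[float], ddof: int = 1, scale: str = "linear"
) -> float:
    """Replicate signal-to-noise: mean / standard deviation across replicates.

    Computed on linear-scale intensities with the sample (n−1) sd by
    default; +inf when the sd is zero.  ``scale="log10"`` applies log10
    first (alternative reading, off by default).
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise ValueError("replicate SNR requires at least 2 replicates")
    if scale == "log10":
        if np.any(arr <= 0):
            raise ValueError("log10 SNR requires positive values")
        arr = np.log10(arr)
    elif scale != "linear":
        raise ValueError(f"unknown scale {scale!r}")
    sd = float(arr.std(ddof=ddof))
    if sd == 0.0:
        return float("inf")
    return float(arr.mean()) / sd


def coefficient_of_variation(values: Sequence[float], ddof: int = 1) -> float:
    """CV in percent: 100 · sd / mean (sample sd); requires positive mean."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise ValueError("CV requires at least 2 values")
    mean = float(arr.mean())
    if mean <= 0:
        raise ValueError("CV requires a positive mean")
    return 100.0 * float(arr.std(ddof=ddof)) / mean


def quantify_run(
    run: Run,
    matches: Sequence[MatchResult],
    targets: Sequence[tuple[str, str, int, float]],
    ppm_tol: float = DEFAULT_PPM_TOL,
    impute: float = DEFAULT_IMPUTE,
) -> pd.DataFrame:
    """Per-protein log10 summed peptide intensity for one run.

    ``targets`` rows are (protein_id, peptide_id, charge, target_mz).  Only
    peptide ions with at least one accepted identification in this run
    contribute; each contributing ion's MS1 intensity is extracted at its
    target m/z, imputed at the threshold when missing, then summed per
    protein and log10-transformed.  Proteins with no accepted ion get a
    MISSING row (imputation of wholly undetected proteins happens at the
    replicate-aggregation stage).
    """
    accepted_keys = {
        (m.peptide_id, m.charge) for m in matches if m.accepted and m.peptide_id
    }
    rows = []
    proteins = sorted({t[0] for t in targets})
    for protein_id in proteins:
        ion_intensities: list[float] = []
        n_accepted = 0
        for prot, peptide_id, charge, target_mz in targets:
            if prot != protein_id:
                continue
            if (peptide_id, charge) not in accepted_keys:
                continue
            n_accepted += 1
            raw = extract_ms1_intensity(run, target_mz, ppm_tol)
            ion_intensities.append(impute_missing(raw, impute))
        rows.append(
            {
                "run_id": run.run_id,
                "protein_id": protein_id,
                "n_accepted_ions": n_accepted,
                "log10_intensity": protein_log_intensity(ion_intensities),
            }
        )
    return pd.DataFrame(rows)


def build_adsorption_table(
    quant: pd.DataFrame,
    impute: float = DEFAULT_IMPUTE,
    snr_threshold: float = DEFAULT_SNR_THRESHOLD,
    snr_scale: str = "linear",
    snr_ddof: int = 1,
) -> pd.DataFrame:
    """Aggregate per-run protein intensities into the polymer × protein table.

    ``quant`` must carry columns polymer_id, replicate, protein_id,
    log10_intensity.  Replicates missing a protein entirely are imputed at
    the threshold intensity before aggregation.  Output rows carry the
    per-replicate log10 intensities, the linear-scale geometric mean, the
    replicate SNR and the filter flag (snr > threshold, strict).
    """
    required = {"polymer_id", "replicate", "protein_id", "log10_intensity"}
    if not required.issubset(quant.columns):
        raise ValueError(f"quant table must have columns {sorted(required)}")
    rows = []
    for (polymer_id, protein_id), grp in quant.groupby(
        ["polymer_id", "protein_id"], sort=True
    ):
        linear = []
        replicate_logs = {}
        for _, rec in grp.sort_values("replicate").iterrows():
            log_val = rec["log10_intensity"]
            lin = impute_missing(
                10.0 ** log_val if not is_missing(log_val) else MISSING, impute
            )
            linear.append(lin)
            replicate_logs[f"log10_rep{int(rec['replicate'])}"] = math.log10(lin)
        geo = geometric_mean(linear)
        snr = (
            replicate_snr(linear, ddof=snr_ddof, scale=snr_scale)
            if len(linear) >= 2
            else float("inf")
        )
        row = {
            "polymer_id": polymer_id,
            "protein_id": protein_id,
            "n_replicates": len(linear),
            "geomean_intensity": geo,
            "log10_geomean": math.log10(geo),
            "snr": snr,
            "passed_filter": snr > snr_threshold,
        }
        row.update(replicate_logs)
        rows.append(row)
    return pd.DataFrame(rows)


def snr_filter(
    table: pd.DataFrame, threshold: float = DEFAULT_SNR_THRESHOLD
) -> pd.DataFrame:
    """Retain rows with snr strictly above threshold; log removals per protein."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    kept = table[table["snr"] > threshold].reset_index(drop=True)
    removed = table[~(table["snr"] > threshold)]
    if len(removed):
        counts = removed.groupby("protein_id").size()
        for protein_id, n in counts.items():
            warnings.warn(
                f"SNR filter removed {n} polymer(s) for {protein_id}", stacklevel=2
            )
    return kept
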