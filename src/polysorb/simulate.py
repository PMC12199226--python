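"""Ground-truthed synthetic data for every pipeline stage.

The generator emulates the study design end to end: a library of
homopolymer chemistries (208 by default) spotted in triplicate, each spot
incubated with the four E8-medium proteins, digested on-surface and read
out by targeted DIA (cycles of 10 one-m/z-window MS2 scans followed by one
MS1 survey over m/z 400–900).  Ground truth is sparse-linear: per protein,
log10 adsorption is an intercept plus a handful of descriptor effects, and
per-replicate amounts add log-normal measurement noise, multiplicative
replicate noise and Bernoulli dropout.  MS1 peptide-ion peaks are
proportional to the adsorbed amount, so the quantification stage can be
validated against the truth exactly (all noise off) or statistically
(default noise).

Every draw is controlled by the configuration seed; identical configs give
bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import e8
from .digest import ProteinEntry, free_peptides, precursor_mz, tryptic_digest
from .library import SpectralLibraryEntry, build_library_from_truth, export_library
from .spectra import AcquisitionScheme, Run, Spectrum, write_run

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate_polymer_library",
    "build_scheme",
    "simulate_dia_run",
    "simulate_study",
    "StudyData",
    "droplet_cap_volume",
    "write_fixture_set",
]


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic generator.

    Defaults reproduce the study conditions: 208 polymers in triplicate,
    four target proteins, 120 descriptors of which 5 drive each protein's
    adsorption, DIA cycles of 10 MS2 scans + 1 MS1 scan over m/z 400–900
    with 1 m/z isolation windows.
    """

    n_polymers: int = 208
    n_replicates: int = 3
    proteins: tuple[ProteinEntry, ...] = e8.E8_PROTEINS
    n_descriptors: int = 120
    n_continuous: int = 10
    n_true_features: int = 5
    coefficient_scale: float = 1.0
    intercept_log10: float = 5.0
    noise_sd_log10: float = 0.15
    replicate_cv: float = 0.2
    dropout_prob: float = 0.1
    n_cycles: int = 10
    cycle_length: int = 10
    ms1_range: tuple[float, float] = (400.0, 900.0)
    isolation_width: float = 1.0
    frag_noise_cv: float = 0.1
    n_noise_peaks: int = 5
    mz_jitter_ppm: float = 3.0
    n_background_peaks: int = 30
    background_intensity: float = 200.0
    peptides_per_protein: int = 5
    min_peptide_length: int = 5
    max_missed_cleavages: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.dropout_prob <= 1.0):
            raise ValueError("dropout_prob must be in [0, 1]")
        if self.n_true_features > self.n_descriptors:
            raise ValueError("n_true_features exceeds n_descriptors")
        for name in ("coefficient_scale", "isolation_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def noiseless(self) -> "SimulationConfig":
        """Copy with every stochastic nuisance disabled (dropout, jitter, noise)."""
        return dataclasses.replace(
            self,
            noise_sd_log10=0.0,
            replicate_cv=0.0,
            dropout_prob=0.0,
            frag_noise_cv=0.0,
            n_noise_peaks=0,
            mz_jitter_ppm=0.0,
            n_background_peaks=0,
        )


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    true_coefficients: pd.DataFrame  # descriptors × proteins, sparse
    intercepts: dict[str, float]
    true_log_adsorption: pd.DataFrame  # polymers × proteins
    replicate_amounts: pd.DataFrame  # rows (polymer, protein, replicate) -> amount
    seed: int

    def true_features(self, protein_id: str) -> list[str]:
        col = self.true_coefficients[protein_id]
        return sorted(col.index[col != 0.0])


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None) -> np.ndarray:
    """Unit-mean multiplicative lognormal noise with the given CV."""
    if cv <= 0:
        return np.ones(size) if size is not None else 1.0
    sigma2 = math.log(1.0 + cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2), size=size)


def generate_polymer_library(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw the descriptor matrix and the sparse-linear adsorption truth.

    Descriptors are mostly small non-negative counts (Poisson, λ=1, named
    ``frag_###`` after signature-count columns) plus a few continuous
    standard-normal columns (``cont_##``).  Per protein,
    true_log_adsorption = intercept + Σ w_j·x_j with exactly
    ``n_true_features`` nonzero w whose magnitudes are uniform in
    [0.5, 1.5]·coefficient_scale with random signs.  Per-replicate linear
    amounts are 10^(truth + N(0, noise_sd_log10)) scaled by unit-mean
    lognormal replicate noise; dropout zeroes a replicate's protein with
    probability dropout_prob.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n_counts = config.n_descriptors - config.n_continuous
    polymer_ids = [f"poly{i:03d}" for i in range(config.n_polymers)]
    names = [f"frag_{i:03d}" for i in range(n_counts)] + [
        f"cont_{i:02d}" for i in range(config.n_continuous)
    ]
    counts = rng.poisson(1.0, size=(config.n_polymers, n_counts)).astype(float)
    cont = rng.standard_normal(size=(config.n_polymers, config.n_continuous))
    X = pd.DataFrame(
        np.hstack([counts, cont]), index=polymer_ids, columns=names
    )
    X.index.name = "polymer_id"

    protein_ids = [p.id for p in config.proteins]
    coef = pd.DataFrame(0.0, index=names, columns=protein_ids)
    intercepts: dict[str, float] = {}
    truth_cols = {}
    for pid in protein_ids:
        chosen = rng.choice(config.n_descriptors, size=config.n_true_features, replace=False)
        magnitudes = rng.uniform(0.5, 1.5, size=config.n_true_features)
        signs = rng.choice([-1.0, 1.0], size=config.n_true_features)
        for j, m, s in zip(chosen, magnitudes, signs):
            coef.iloc[j, coef.columns.get_loc(pid)] = s * m * config.coefficient_scale
        intercepts[pid] = config.intercept_log10
        truth_cols[pid] = intercepts[pid] + X.to_numpy() @ coef[pid].to_numpy()
    truth = pd.DataFrame(truth_cols, index=polymer_ids)
    truth.index.name = "polymer_id"

    rows = []
    for polymer_id in polymer_ids:
        for pid in protein_ids:
            base = truth.loc[polymer_id, pid]
            for rep in range(config.n_replicates):
                if rng.uniform() < config.dropout_prob:
                    amount = 0.0
                else:
                    log_amount = base + rng.normal(0.0, config.noise_sd_log10)
                    amount = 10.0 ** log_amount * float(
                        _lognormal_factor(rng, config.replicate_cv)
                    )
                rows.append(
                    {
                        "polymer_id": polymer_id,
                        "protein_id": pid,
                        "replicate": rep,
                        "amount": amount,
                    }
                )
    amounts = pd.DataFrame(rows)
    return X, GroundTruth(
        true_coefficients=coef,
        intercepts=intercepts,
        true_log_adsorption=truth,
        replicate_amounts=amounts,
        seed=config.seed,
    )


def build_scheme(
    config: SimulationConfig,
) -> tuple[AcquisitionScheme, list[SpectralLibraryEntry], pd.DataFrame, dict[tuple[str, int], float]]:
    """Targets, ground-truth library, target table and response factors.

    Insulin is monitored through its single free peptide GFFYTPK at charges
    1 and 2; every other protein through its top-k free tryptic peptides
    (complete digest) whose doubly charged precursors fall inside the MS1
    range, ordered by descending m/z.  Per-ion response factors sum to 1
    within each protein so that, noise aside, the summed extracted MS1
    intensity of a protein equals its adsorbed amount.
    """
    lo, hi = config.ms1_range
    targets: list[tuple[str, int, float]] = []
    table_rows = []
    all_peptides = []
    for protein in config.proteins:
        digest = tryptic_digest(protein, max_missed=config.max_missed_cleavages)
        free = free_peptides(protein, digest, min_length=config.min_peptide_length)
        # unique by sequence, deterministic order
        unique = {p.sequence: p for p in free}
        if protein.id == "insulin":
            candidates = [
                (pep, z)
                for pep in unique.values()
                for z in (1, 2)
                if lo <= precursor_mz(pep.monoisotopic_mass, z) < hi
            ]
        else:
            with_mz = [
                (pep, 2)
                for pep in unique.values()
                if lo <= precursor_mz(pep.monoisotopic_mass, 2) < hi
            ]
            with_mz.sort(key=lambda t: -precursor_mz(t[0].monoisotopic_mass, t[1]))
            candidates = with_mz[: config.peptides_per_protein]
        for pep, z in candidates:
            mz = precursor_mz(pep.monoisotopic_mass, z)
            targets.append((pep.sequence, z, mz))
            table_rows.append(
                {
                    "protein_id": protein.id,
                    "peptide_id": pep.sequence,
                    "charge": z,
                    "target_mz": mz,
                }
            )
            all_peptides.append((pep, z))
    target_table = pd.DataFrame(table_rows)
    response_factors: dict[tuple[str, int], float] = {}
    for protein_id, grp in target_table.groupby("protein_id"):
        rf = 1.0 / len(grp)
        for _, row in grp.iterrows():
            response_factors[(row["peptide_id"], row["charge"])] = rf
    entries: list[SpectralLibraryEntry] = []
    for pep, z in all_peptides:
        entries.extend(build_library_from_truth([pep], [z]))
    scheme = AcquisitionScheme(
        targets=targets,
        isolation_width=config.isolation_width,
        ms1_range=config.ms1_range,
        cycle_length=config.cycle_length,
    )
    return scheme, entries, target_table, response_factors


def _assemble(mz: list[float], intensity: list[float]) -> tuple[np.ndarray, np.ndarray]:
    """Sort peaks ascending, merging exact m/z duplicates by summing."""
    if not mz:
        return np.array([]), np.array([])
    order = np.argsort(mz, kind="stable")
    mz_a = np.asarray(mz, dtype=float)[order]
    int_a = np.asarray(intensity, dtype=float)[order]
    uniq, inverse = np.unique(mz_a, return_inverse=True)
    if uniq.size != mz_a.size:
        summed = np.zeros_like(uniq)
        np.add.at(summed, inverse, int_a)
        return uniq, summed
    return mz_a, int_a


def simulate_dia_run(
    run_id: str,
    amounts: Mapping[str, float],
    library: Sequence[SpectralLibraryEntry],
    scheme: AcquisitionScheme,
    target_table: pd.DataFrame,
    response_factors: Mapping[tuple[str, int], float],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> Run:
    """Simulate one polymer-spot acquisition.

    MS2 scans cycle round-robin through the scheme targets; after every
    ``cycle_length`` MS2 scans an MS1 survey scan is inserted, for
    ``n_cycles`` cycles.  A target whose protein dropped out (amount 0)
    contributes no fragment or precursor peaks.  MS1 peptide peaks sit at
    the precursor m/z (± uniform ppm jitter) with intensity amount ×
    response factor × unit-mean lognormal noise, on top of uniform
    background peaks.
    """
    lib_by_key = {e.key: e for e in library}
    protein_of = dict(
        zip(
            zip(target_table["peptide_id"], target_table["charge"]),
            target_table["protein_id"],
        )
    )
    lo, hi = scheme.ms1_range
    spectra: list[Spectrum] = []
    scan_id = 0
    target_cursor = 0
    n_targets = len(scheme.targets)
    for _cycle in range(config.n_cycles):
        for _ in range(scheme.cycle_length):
            peptide_id, charge, prec_mz = scheme.targets[target_cursor % n_targets]
            target_cursor += 1
            scan_id += 1
            entry = lib_by_key[(peptide_id, charge)]
            amount = amounts.get(protein_of[(peptide_id, charge)], 0.0)
            mz_list: list[float] = []
            int_list: list[float] = []
            if amount > 0:
                noise = _lognormal_factor(rng, config.frag_noise_cv, entry.fragment_mz.size)
                mz_list.extend(entry.fragment_mz.tolist())
                int_list.extend((entry.fragment_intensity * noise).tolist())
            for _n in range(config.n_noise_peaks):
                mz_list.append(float(rng.uniform(100.0, 1500.0)))
                int_list.append(float(rng.uniform(10.0, 60.0)))
            mz_arr, int_arr = _assemble(mz_list, int_list)
            spectra.append(
                Spectrum(
                    scan_id=scan_id,
                    ms_level=2,
                    mz=mz_arr,
                    intensity=int_arr,
                    precursor_mz=prec_mz,
                    isolation_width=scheme.isolation_width,
                )
            )
        # MS1 survey scan
        scan_id += 1
        mz_list, int_list = [], []
        for peptide_id, charge, prec_mz in scheme.targets:
            amount = amounts.get(protein_of[(peptide_id, charge)], 0.0)
            if amount <= 0 or not (lo <= prec_mz <= hi):
                continue
            jitter = (
                rng.uniform(-config.mz_jitter_ppm, config.mz_jitter_ppm) * 1e-6
                if config.mz_jitter_ppm > 0
                else 0.0
            )
            rf = response_factors[(peptide_id, charge)]
            mz_list.append(prec_mz * (1.0 + jitter))
            int_list.append(
                amount * rf * float(_lognormal_factor(rng, config.frag_noise_cv))
            )
        for _n in range(config.n_background_peaks):
            mz_list.append(float(rng.uniform(lo, hi)))
            int_list.append(float(rng.uniform(0.1, 1.0)) * config.background_intensity)
        mz_arr, int_arr = _assemble(mz_list, int_list)
        spectra.append(
            Spectrum(
                scan_id=scan_id,
                ms_level=1,
                mz=mz_arr,
                intensity=int_arr,
                scan_range=scheme.ms1_range,
            )
        )
    return Run(run_id=run_id, spectra=spectra, cycle_length=scheme.cycle_length)


@dataclass
class StudyData:
    """One simulated study: inputs for every downstream stage plus the truth."""

    config: SimulationConfig
    descriptors: pd.DataFrame
    ground_truth: GroundTruth
    scheme: AcquisitionScheme
    library: list[SpectralLibraryEntry]
    target_table: pd.DataFrame
    response_factors: dict[tuple[str, int], float]
    runs: dict[str, Run]
    run_meta: pd.DataFrame  # run_id, polymer_id, replicate


def simulate_study(config: SimulationConfig) -> StudyData:
    """Generate the full study: descriptors, truth and one run per spot."""
    X, truth = generate_polymer_library(config)
    scheme, library, target_table, response_factors = build_scheme(config)
    amounts = truth.replicate_amounts.set_index(
        ["polymer_id", "replicate", "protein_id"]
    )["amount"].sort_index()
    runs: dict[str, Run] = {}
    meta_rows = []
    for pi, polymer_id in enumerate(truth.true_log_adsorption.index):
        for rep in range(config.n_replicates):
            rng = np.random.default_rng(
                np.random.SeedSequence([config.seed, 2, pi, rep])
            )
            per_protein = amounts.loc[polymer_id, rep].to_dict()
            run_id = f"{polymer_id}_r{rep}"
            runs[run_id] = simulate_dia_run(
                run_id,
                per_protein,
                library,
                scheme,
                target_table,
                response_factors,
                config,
                rng,
            )
            meta_rows.append(
                {"run_id": run_id, "polymer_id": polymer_id, "replicate": rep}
            )
    return StudyData(
        config=config,
        descriptors=X,
        ground_truth=truth,
        scheme=scheme,
        library=library,
        target_table=target_table,
        response_factors=response_factors,
        runs=runs,
        run_meta=pd.DataFrame(meta_rows),
    )


def droplet_cap_volume(contact_radius_mm: float, contact_angle_deg: float) -> float:
    """Spherical-cap droplet volume in nL from contact radius (mm) and angle.

    V = (π a³ / 3) · (1 − cos θ)² (2 + cos θ) / sin³ θ, converted mm³→nL.
    At θ = 90° this is the hemisphere 2πa³/3.  Note that for a 0.7 mm
    contact radius and a 5.2° contact angle the closed form gives ≈ 24.5 nL
    (see the methods note on the geometry of sessile digestion droplets).
    """
    if contact_radius_mm <= 0:
        raise ValueError("contact radius must be > 0")
    if not (0.0 < contact_angle_deg < 180.0):
        raise ValueError("contact angle must be in (0, 180) degrees")
    theta = math.radians(contact_angle_deg)
    a = contact_radius_mm
    volume_mm3 = (
        (math.pi * a**3 / 3.0)
        * (1.0 - math.cos(theta)) ** 2
        * (2.0 + math.cos(theta))
        / math.sin(theta) ** 3
    )
    return volume_mm3 * 1000.0  # 1 mm³ = 1 µL = 1000 nL


def write_fixture_set(config: SimulationConfig, out_dir: str | Path) -> list[Path]:
    """Materialise a study on disk: run tables, library, descriptors, truth, manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    study = simulate_study(config)
    written: list[Path] = []
    for run_id, run in study.runs.items():
        path = out / f"{run_id}.runtable.csv"
        write_run(run, path)
        written.append(path)
    lib_path = out / "library.csv"
    export_library(study.library, lib_path)
    written.append(lib_path)
    desc_path = out / "descriptors.csv"
    study.descriptors.to_csv(desc_path)
    written.append(desc_path)
    truth_path = out / "ground_truth.csv"
    study.ground_truth.true_log_adsorption.to_csv(truth_path)
    written.append(truth_path)
    manifest = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
            if k != "proteins"
        },
        "proteins": [p.id for p in config.proteins],
        "n_runs": len(study.runs),
        "targets": [
            {"peptide_id": t[0], "charge": t[1], "precursor_mz": t[2]}
            for t in study.scheme.targets
        ],
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    written.append(manifest_path)
    return written
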