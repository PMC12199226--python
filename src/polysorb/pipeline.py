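"""End-to-end orchestration: simulate → identify → quantify → model.

A single configuration (TOML file or nested dict) drives every stage with
one global seed; stage seeds derive from it so a rerun with the same
configuration is bit-identical.  The report counts what each stage
produced (scans, accepted identifications, polymers passing the SNR
filter, selected features, test metrics) so a run can be audited against
the configured thresholds.
"""

from __future__ import annotations

import dataclasses
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

from .library import (
    DEFAULT_COS_MIN,
    DEFAULT_FRAG_TOL,
    DEFAULT_MIN_FRAG,
    identify_run,
)
from .model import ModelConfig, ProteinAdsorptionModel
from .quantify import (
    DEFAULT_IMPUTE,
    DEFAULT_PPM_TOL,
    DEFAULT_SNR_THRESHOLD,
    build_adsorption_table,
    quantify_run,
    snr_filter,
)
from .simulate import SimulationConfig, simulate_study

__all__ = ["PipelineConfig", "run_pipeline", "validate_config", "load_config"]


@dataclass
class MatchConfig:
    frag_tol: float = DEFAULT_FRAG_TOL
    cos_min: float = DEFAULT_COS_MIN
    min_frag: int = DEFAULT_MIN_FRAG


@dataclass
class QuantifyConfig:
    ppm_tol: float = DEFAULT_PPM_TOL
    impute: float = DEFAULT_IMPUTE
    snr_threshold: float = DEFAULT_SNR_THRESHOLD
    snr_scale: str = "linear"


@dataclass
class PipelineConfig:
    """All stage configurations plus the global seed and output directory."""

    seed: int = 0
    out_dir: str = "polysorb_out"
    run_model: bool = True
    simulate: SimulationConfig = field(default_factory=SimulationConfig)
    match: MatchConfig = field(default_factory=MatchConfig)
    quantify: QuantifyConfig = field(default_factory=QuantifyConfig)
    model: ModelConfig = field(default_factory=ModelConfig)

    def __post_init__(self) -> None:
        # stage seeds derive from the global seed
        self.simulate = dataclasses.replace(self.simulate, seed=self.seed)
        self.model = dataclasses.replace(self.model, seed=self.seed + 1)


_KNOWN_SECTIONS = {"simulate", "match", "quantify", "model"}


def load_config(path: str | Path) -> PipelineConfig:
    """Read a TOML pipeline configuration."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    diagnostics = validate_mapping(raw)
    errors = [d for d in diagnostics if d.startswith("error")]
    if errors:
        raise ValueError("invalid configuration: " + "; ".join(errors))
    return _config_from_mapping(raw)


def _config_from_mapping(raw: dict[str, Any]) -> PipelineConfig:
    def build(cls, section):
        fields = {f.name for f in dataclasses.fields(cls)}
        kwargs = {k: v for k, v in raw.get(section, {}).items() if k in fields}
        if "ms1_range" in kwargs:
            kwargs["ms1_range"] = tuple(kwargs["ms1_range"])
        return cls(**kwargs)

    return PipelineConfig(
        seed=int(raw.get("seed", 0)),
        out_dir=str(raw.get("out", raw.get("out_dir", "polysorb_out"))),
        run_model=bool(raw.get("run_model", True)),
        simulate=build(SimulationConfig, "simulate"),
        match=build(MatchConfig, "match"),
        quantify=build(QuantifyConfig, "quantify"),
        model=build(ModelConfig, "model"),
    )


def validate_mapping(raw: dict[str, Any]) -> list[str]:
    """Diagnostics (error:/warning: prefixed strings) for a raw config mapping."""
    out: list[str] = []
    for section in raw:
        if isinstance(raw[section], dict) and section not in _KNOWN_SECTIONS:
            out.append(f"warning: unknown section [{section}]")
    for section, cls in (
        ("simulate", SimulationConfig),
        ("match", MatchConfig),
        ("quantify", QuantifyConfig),
        ("model", ModelConfig),
    ):
        body = raw.get(section, {})
        if not isinstance(body, dict):
            out.append(f"error: section [{section}] is not a table")
            continue
        known = {f.name for f in dataclasses.fields(cls)}
        for key in body:
            if key not in known:
                out.append(f"warning: unknown key {key!r} in [{section}]")
    match = raw.get("match", {})
    if isinstance(match, dict):
        if "cos_min" in match and not (0.0 <= match["cos_min"] <= 1.0):
            out.append("error: match.cos_min outside [0, 1]")
        if "frag_tol" in match and match["frag_tol"] <= 0:
            out.append("error: match.frag_tol must be > 0")
    quantify = raw.get("quantify", {})
    if isinstance(quantify, dict):
        if "snr_threshold" in quantify and quantify["snr_threshold"] <= 0:
            out.append("error: quantify.snr_threshold must be > 0")
        if "ppm_tol" in quantify and quantify["ppm_tol"] <= 0:
            out.append("error: quantify.ppm_tol must be > 0")
    model = raw.get("model", {})
    if isinstance(model, dict) and "train_fraction" in model:
        if not (0.0 < model["train_fraction"] < 1.0):
            out.append("error: model.train_fraction outside (0, 1)")
    return out


def validate_config(path: str | Path) -> list[str]:
    """Validate a TOML configuration file without side effects."""
    try:
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
    except (OSError, tomllib.TOMLDecodeError) as exc:
        return [f"error: cannot read configuration: {exc}"]
    return validate_mapping(raw)


def run_pipeline(config: PipelineConfig, write_outputs: bool = True) -> dict[str, Any]:
    """Execute every enabled stage; returns the run report.

    Stage order: simulate → identify → quantify/aggregate/filter →
    (optionally) model per protein.  Outputs land in ``config.out_dir``;
    the report is also written there as report.json.
    """
    out = Path(config.out_dir)
    if write_outputs:
        out.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {"seed": config.seed, "stages": {}}

    study = simulate_study(config.simulate)
    n_scans = sum(len(r.spectra) for r in study.runs.values())
    report["stages"]["simulate"] = {
        "n_runs": len(study.runs),
        "n_scans": n_scans,
        "n_targets": len(study.scheme.targets),
        "n_polymers": config.simulate.n_polymers,
    }

    quant_rows = []
    n_ms2 = 0
    n_accepted = 0
    targets = list(
        study.target_table[["protein_id", "peptide_id", "charge", "target_mz"]]
        .itertuples(index=False, name=None)
    )
    meta = study.run_meta.set_index("run_id")
    for run_id, run in study.runs.items():
        matches = identify_run(
            run,
            study.library,
            study.scheme,
            frag_tol=config.match.frag_tol,
            cos_min=config.match.cos_min,
            min_frag=config.match.min_frag,
        )
        n_ms2 += len(matches)
        n_accepted += sum(m.accepted for m in matches)
        q = quantify_run(
            run,
            matches,
            targets,
            ppm_tol=config.quantify.ppm_tol,
            impute=config.quantify.impute,
        )
        q["polymer_id"] = meta.loc[run_id, "polymer_id"]
        q["replicate"] = meta.loc[run_id, "replicate"]
        quant_rows.append(q)
    quant = pd.concat(quant_rows, ignore_index=True)
    report["stages"]["match"] = {"n_ms2_scans": n_ms2, "n_accepted": n_accepted}

    table = build_adsorption_table(
        quant,
        impute=config.quantify.impute,
        snr_threshold=config.quantify.snr_threshold,
        snr_scale=config.quantify.snr_scale,
    )
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        filtered = snr_filter(table, config.quantify.snr_threshold)
    survivors = (
        filtered.groupby("protein_id").size().to_dict() if len(filtered) else {}
    )
    report["stages"]["quantify"] = {
        "n_rows": len(table),
        "snr_survivors": {k: int(v) for k, v in survivors.items()},
    }
    if write_outputs:
        quant.to_csv(out / "quant.csv", index=False)
        table.to_csv(out / "adsorption.csv", index=False)
        study.descriptors.to_csv(out / "descriptors.csv")

    if config.run_model:
        model_report = {}
        for protein in study.ground_truth.true_log_adsorption.columns:
            try:
                model = ProteinAdsorptionModel.from_tables(
                    table, study.descriptors, protein, config.model
                )
            except ValueError as exc:
                model_report[protein] = {"skipped": str(exc)}
                continue
            try:
                boot = model.fit_bootstrap()
            except ValueError as exc:  # e.g. too few SNR survivors to split
                model_report[protein] = {"skipped": str(exc)}
                continue
            ranked = boot.ranked_features()
            n_sig = int(ranked["significant"].sum())
            model_report[protein] = {
                "n_polymers": len(model.y),
                "mean_rmse": boot.mean_rmse,
                "mean_r2": boot.mean_r2,
                "n_significant_features": n_sig,
            }
            if write_outputs:
                boot.metrics_frame().to_csv(
                    out / f"metrics_{protein}.csv", index=False
                )
                ranked.to_csv(out / f"features_{protein}.csv", index=False)
        report["stages"]["model"] = model_report

    if write_outputs:
        (out / "report.json").write_text(json.dumps(report, indent=1, default=str))
    return report
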