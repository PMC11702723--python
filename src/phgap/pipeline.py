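"""End-to-end runs from a single validated config, with reproducibility
metadata (config hash + seed stamped into every report)."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from . import gap_kinetics as gk
from . import pre_forward as pf
from . import synthetic_data as sd

__all__ = ["RunConfig", "PreConfig", "KineticsConfig", "PipelineError",
           "load_config", "run_pre_pipeline", "run_kinetics_pipeline"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


class PreConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    source: Literal["synthetic"] = "synthetic"
    rho_major: float = Field(0.9, ge=0.0, le=1.0)
    noise_sd: float = Field(0.0, ge=0.0)
    n_models: int = Field(10, ge=1)
    n_label_candidates: int = Field(200, ge=1)
    jitter: float = Field(0.5, ge=0.0)
    r2: float = Field(100.0, gt=0.0)
    proton_frequency: float = Field(850e6, gt=0.0)
    observed_ratios: Optional[str] = None  # TSV overriding the synthetic table


class ConditionConfig(BaseModel):
    # "construct" (the YAML key) shadows a deprecated BaseModel classmethod,
    # hence the aliased internal name
    model_config = ConfigDict(extra="forbid", populate_by_name=True)

    construct_name: str = Field(alias="construct")
    pip2_mol_percent: float = 5.0
    accessible_lipid: float = 0.5e-3
    arf_total: float = 1e-6
    ph_total: float = 0.0
    endpoint: float = 180.0
    dose_response: Optional[str] = None  # CSV (enzyme_M, fraction[, sd])

    def to_condition(self) -> gk.AssayCondition:
        return gk.AssayCondition(
            construct=self.construct_name, pip2_mol_percent=self.pip2_mol_percent,
            accessible_lipid=self.accessible_lipid, arf_total=self.arf_total,
            ph_total=self.ph_total, endpoint=self.endpoint)


class KineticsConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    conditions: list[ConditionConfig]
    free_parameters: list[str] = []
    n_starts: int = Field(3, ge=1)
    noise_sd: float = Field(0.05, ge=0.0)
    parameters: dict[str, float] = {}
    decompose: bool = True


class RunConfig(BaseModel):
    """Schema-validated single-file run configuration (unknown keys rejected)."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    out_dir: str = "phgap_out"
    log_level: str = "INFO"
    pre: Optional[PreConfig] = None
    kinetics: Optional[KineticsConfig] = None

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(**raw)


def _stamp(config: RunConfig) -> dict:
    return {"version": __version__, "config_hash": config.config_hash(),
            "seed": config.seed}


def run_pre_pipeline(config: RunConfig) -> dict:
    """Label placement -> per-pose forward profiles -> two-state fit.

    Writes report.json and per-methyl TSVs under the configured output
    directory and returns the report dict.
    """
    if config.pre is None:
        raise PipelineError("validation", "config has no 'pre' block")
    cfg = config.pre
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if cfg.observed_ratios is not None and not Path(cfg.observed_ratios).exists():
        raise PipelineError("validation", f"observed ratios file {cfg.observed_ratios} not found")

    try:
        pose_a, pose_b, site = sd.make_two_pose_ensemble(
            seed=config.seed, n_models=cfg.n_models, jitter=cfg.jitter)
    except Exception as exc:  # noqa: BLE001 - stage attribution
        raise PipelineError("ensembles", str(exc)) from exc

    params = pf.RelaxationParams(proton_frequency=cfg.proton_frequency)
    try:
        observed, prof_a, prof_b = sd.synth_pre_dataset(
            pose_a, pose_b, site, rho_major=cfg.rho_major,
            noise_sd=cfg.noise_sd, params=params, seed=config.seed,
            r2=cfg.r2, n_label_candidates=cfg.n_label_candidates)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("forward", str(exc)) from exc
    if cfg.observed_ratios is not None:
        observed = pd.read_csv(cfg.observed_ratios, sep="\t")

    prof_a.to_csv(out / "profile_pose_a.tsv", sep="\t", index=False)
    prof_b.to_csv(out / "profile_pose_b.tsv", sep="\t", index=False)
    observed.to_csv(out / "observed_ratios.tsv", sep="\t", index=False)

    try:
        fit = pf.fit_two_state(observed, prof_a, prof_b, params, r2=cfg.r2)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("fit", str(exc)) from exc

    report = {
        **_stamp(config),
        "stage": "pre",
        "n_methyls": int(len(observed)),
        "rho_major": fit.rho_major,
        "rho_a": fit.rho_a,
        "major_state": fit.major_state,
        "major_minor_ratio": fit.major_minor_ratio,
        "slope": fit.slope,
        "pearson_r": fit.pearson_r,
        "residual_norm": fit.residual_norm,
        "degenerate": fit.degenerate,
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def run_kinetics_pipeline(config: RunConfig) -> dict:
    """Simulate/fit dose-response sets; C50 table + scenario decomposition."""
    if config.kinetics is None:
        raise PipelineError("validation", "config has no 'kinetics' block")
    cfg = config.kinetics
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    for cc in cfg.conditions:
        if cc.dose_response is not None and not Path(cc.dose_response).exists():
            raise PipelineError("validation", f"dose-response file {cc.dose_response} not found")

    params = gk.RateParameters(**{**cfg.parameters})
    conditions = [cc.to_condition() for cc in cfg.conditions]

    try:
        datasets = []
        synth_needed = [c for c, cc in zip(conditions, cfg.conditions)
                        if cc.dose_response is None]
        synth = dict(zip(synth_needed, [t for _, t in sd.synth_dose_response(
            synth_needed, params, noise_sd=cfg.noise_sd, seed=config.seed)])) \
            if synth_needed else {}
        for c, cc in zip(conditions, cfg.conditions):
            table = (pd.read_csv(cc.dose_response) if cc.dose_response is not None
                     else synth[c])
            datasets.append((c, table))
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("data", str(exc)) from exc

    try:
        fit = gk.fit_global(datasets, free=cfg.free_parameters, fixed=params,
                            n_starts=cfg.n_starts, seed=config.seed)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("fit", str(exc)) from exc

    report = {
        **_stamp(config),
        "stage": "kinetics",
        "loss": fit.loss,
        "identifiability_warning": fit.identifiability_warning,
        "parameters": {k: getattr(fit.params, k) for k in (
            "kon_pip2", "koff_pip2", "kon_pa", "koff_pa", "kon_z", "koff_z",
            "kcat0", "alpha", "gamma", "tether_eff")},
    }
    fit.per_start.to_csv(out / "fit_starts.tsv", sep="\t", index=False)

    if cfg.decompose:
        try:
            table = gk.decompose_enhancement(fit.params, conditions[0])
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("decompose", str(exc)) from exc
        table.to_csv(out / "scenario_shifts.tsv", sep="\t", index=False)
        report["scenario_shifts"] = {
            r.scenario: r.log10_shift for r in table.itertuples()}

    c50s = {}
    for c, table in datasets:
        try:
            c50s[c.construct] = gk.c50_from_data(table)
        except ValueError:
            c50s[c.construct] = None
    report["c50_from_data"] = c50s

    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
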