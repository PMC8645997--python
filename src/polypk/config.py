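"""Structured run configuration (YAML mapping) with strict key checking."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .estimation import FitSettings
from .pk_core import PKParameters
from .population_model import PopulationModel
from .synthetic_data import StudyDesign

__all__ = ["RunConfig", "load_config", "model_from_dict", "model_to_dict"]


class ConfigError(ValueError):
    pass


def _check_keys(block: dict, allowed: set[str], where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"unknown keys in {where}: {sorted(unknown)}")


def model_from_dict(d: dict) -> PopulationModel:
    _check_keys(d, {"theta", "omega2", "sigma", "residual_model"}, "model")
    theta = d.get("theta", {})
    _check_keys(theta, {"V", "V2", "CL", "Q"}, "model.theta")
    defaults = PopulationModel()
    tv = {k: float(theta.get(k, getattr(defaults.theta, k))) for k in ("V", "V2", "CL", "Q")}
    omega2 = {k: float(v) for k, v in d.get("omega2", defaults.omega2).items()}
    return PopulationModel(
        theta=PKParameters(**tv),
        omega2=omega2,
        sigma=float(d.get("sigma", defaults.sigma)),
        residual_model=d.get("residual_model", "proportional"),
    )


def model_to_dict(model: PopulationModel) -> dict:
    import numpy as np

    return {
        "theta": {k: float(np.asarray(getattr(model.theta, k))) for k in ("V", "V2", "CL", "Q")},
        "omega2": dict(model.omega2),
        "sigma": model.sigma,
        "residual_model": model.residual_model,
    }


def _design_from_dict(d: dict) -> StudyDesign:
    names = {f.name for f in fields(StudyDesign)}
    _check_keys(d, names, "design")
    kwargs = {}
    for k, v in d.items():
        kwargs[k] = tuple(v) if isinstance(v, list) else v
    return StudyDesign(**kwargs)


def _settings_from_dict(d: dict) -> FitSettings:
    names = {f.name for f in fields(FitSettings)}
    _check_keys(d, names, "estimation")
    return FitSettings(**d)


@dataclass
class RunConfig:
    """Model, study design, estimation settings and simulation block."""

    model: PopulationModel = field(default_factory=PopulationModel)
    design: StudyDesign = field(default_factory=StudyDesign)
    estimation: FitSettings = field(default_factory=FitSettings)
    simulation: dict = field(default_factory=dict)
    seed: int = 0

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        _check_keys(raw, {"model", "design", "estimation", "simulation", "seed"}, "config")
        sim = raw.get("simulation", {})
        _check_keys(
            sim,
            {"n_subjects", "mic_grid", "regimens", "ss_mode",
             "target_low", "target_high", "toxicity_threshold"},
            "simulation",
        )
        return cls(
            model=model_from_dict(raw.get("model", {})),
            design=_design_from_dict(raw.get("design", {})),
            estimation=_settings_from_dict(raw.get("estimation", {})),
            simulation=sim,
            seed=int(raw.get("seed", 0)),
        )


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    return RunConfig.from_dict(raw)
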