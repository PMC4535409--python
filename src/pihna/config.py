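"""Run configuration: schema, loading, validation, serialization.

Configurations are YAML (or JSON) documents with four sections -- model,
solver, cohort, therapy -- validated against a strict schema: unknown
keys are rejected and every violation is reported with its field path.
The radiotherapy alpha-rho coefficients have no defaults anywhere in the
code; a run that needs radiation fails loudly unless the configuration
provides them.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, model_validator

from .cohort import CohortGrid, build_cohort
from .imaging import ImagingThresholds
from .parameters import PihnaParameters, SolverSettings
from .therapy import AAEffect, RadiotherapyPlan

__all__ = ["RunConfig", "ConfigError", "load_config", "dump_config",
           "default_config_path"]


class ConfigError(ValueError):
    """A configuration file failed validation."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)


class ModelSection(_Strict):
    """Model constants; domain-type invariants are enforced at load time."""

    D: float = 305.0
    rho: float = 83.0
    K: float = 2.39e5
    D_h: float | None = None
    D_v: float | None = None
    D_a: float = 3139.0
    hypoxia_rate: float = 0.02
    reoxygenation_rate: float = 0.1
    necrosis_rate: float = 0.05
    vascular_sufficiency_threshold: float = 0.05
    vascular_sufficiency_width: float = 0.005
    necrosis_threshold: float = 0.03
    vessel_growth_rate: float = 0.1
    a_halfsat: float = 1.0
    a_production_h: float = 40.0
    a_production_c: float = 0.4
    a_decay: float = 2.0
    a_uptake_vessel: float = 1.0
    a_consumption_growth: float = 10.0
    vessel_destabilization_rate: float = 0.12
    a_destabilization_halfsat: float = 3.0
    vascular_fraction_normal: float = 0.05

    def to_params(self) -> PihnaParameters:
        return PihnaParameters(**self.model_dump())

    @model_validator(mode="after")
    def _invariants(self) -> "ModelSection":
        self.to_params()
        return self


class SolverSection(_Strict):
    dr: float = 0.25
    r_max: float = 100.0
    rtol: float = 1e-5
    atol_density: float = 1.0
    atol_a: float = 1e-6
    event_tol: float = 0.1
    max_horizon: float = 15000.0

    def to_settings(self) -> SolverSettings:
        return SolverSettings(**self.model_dump())

    @model_validator(mode="after")
    def _invariants(self) -> "SolverSection":
        self.to_settings()
        return self


class CohortSection(_Strict):
    rho_bounds: tuple[float, float] = (8.3, 83.0)
    n_rho: int = 11
    D_bounds: tuple[float, float] = (1.43, 143.0)
    n_D: int = 13
    start_sizes_cm: tuple[float, ...] = (1.5, 2.5, 3.5)

    def to_cohort(self) -> CohortGrid:
        return build_cohort(self.rho_bounds, self.n_rho, self.D_bounds,
                            self.n_D, self.start_sizes_cm)


class AASection(_Strict):
    angiogenic_action_factor: float = 100.0
    h_to_c_multiplier: float = 2.0
    c_to_h_multiplier: float = 0.5
    duration_days: float = 42.0

    def to_effect(self) -> AAEffect:
        return AAEffect(**self.model_dump())

    @model_validator(mode="after")
    def _invariants(self) -> "AASection":
        self.to_effect()
        return self


class RadiotherapySection(_Strict):
    # alpha coefficients are deliberately optional here so that a config
    # without radiation experiments still validates; to_plan() enforces them
    alpha_slope: float | None = None
    alpha_intercept: float | None = None
    dose_per_fraction: float = 2.0
    n_fractions: int = 30
    alpha_beta_ratio: float = 10.0
    oer_max: float = 3.0

    def to_plan(self) -> RadiotherapyPlan:
        if self.alpha_slope is None or self.alpha_intercept is None:
            raise ConfigError(
                "therapy.radiotherapy.alpha_slope and alpha_intercept map the "
                "net proliferation rate to the LQ radiosensitivity and have no "
                "defaults; set both in the configuration file")
        return RadiotherapyPlan(
            alpha_slope=self.alpha_slope, alpha_intercept=self.alpha_intercept,
            dose_per_fraction=self.dose_per_fraction,
            n_fractions=self.n_fractions,
            alpha_beta_ratio=self.alpha_beta_ratio, oer_max=self.oer_max)


class TherapySection(_Strict):
    aa: AASection = AASection()
    radiotherapy: RadiotherapySection = RadiotherapySection()


class ImagingSection(_Strict):
    t1gd_fraction: float = 0.80
    t2_fraction: float = 0.16

    def to_thresholds(self) -> ImagingThresholds:
        return ImagingThresholds(**self.model_dump())

    @model_validator(mode="after")
    def _invariants(self) -> "ImagingSection":
        self.to_thresholds()
        return self


class RunConfig(_Strict):
    model: ModelSection = ModelSection()
    solver: SolverSection = SolverSection()
    cohort: CohortSection = CohortSection()
    therapy: TherapySection = TherapySection()
    imaging: ImagingSection = ImagingSection()

    def resolved(self) -> dict:
        """Fully resolved configuration as plain data (manifest payload)."""
        return self.model_dump(mode="json")


def default_config_path() -> Path:
    return Path(__file__).parent / "data" / "default_config.yaml"


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a YAML/JSON run configuration.

    With no path, the packaged default configuration is used.  Schema
    violations raise :class:`ConfigError` naming the offending fields.
    """
    path = Path(path) if path is not None else default_config_path()
    if not path.exists():
        raise FileNotFoundError(f"configuration file not found: {path}")
    text = path.read_text()
    raw = (json.loads(text) if path.suffix.lower() == ".json"
           else yaml.safe_load(text)) or {}
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        paths = "; ".join(
            ".".join(str(p) for p in err["loc"]) + f": {err['msg']}"
            for err in exc.errors())
        raise ConfigError(f"invalid configuration {path}: {paths}") from exc


def dump_config(config: RunConfig, path: str | Path) -> None:
    """Write a resolved configuration back to YAML/JSON (round-trippable)."""
    path = Path(path)
    data = config.resolved()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=True))
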