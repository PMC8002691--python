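"""Run configuration: isotope constants, tracer additions, detection limits.

Loaded from YAML; unknown keys are rejected so typos fail loudly rather
than silently falling back to defaults.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .errors import ConfigError
from .isotope import R_AIR, IsotopeConstants


class TracerDose(BaseModel):
    """Amount and isotopic purity of one tracer addition to a bottle."""

    model_config = ConfigDict(extra="forbid")

    added_nmol: float = Field(gt=0)
    purity_fraction: float = Field(gt=0, le=1)


class RunConfig(BaseModel):
    """Everything the pipeline needs besides the data tables.

    Defaults encode the cruise design: 0.1 mL of 5 mM ¹⁵NO₃⁻ (500 nmol) or
    0.1 mL of 0.8 mM ¹⁵NH₄⁺ (80 nmol), both 99 atom-% ¹⁵N, added to 120 mL
    bottles holding 118 mL of seawater under a 2 mL helium headspace; a
    1.0 nmol N instrument detection limit for N₂O; ambient-nutrient
    detection limits of 0.2 µmol L⁻¹ (NO₃⁻) and 15 nmol L⁻¹ (NH₄⁺); and an
    oxic–anoxic interface criterion of O₂ < 1.0 µM.
    """

    model_config = ConfigDict(extra="forbid")

    r_ref: float = R_AIR
    r_air: float = R_AIR
    liquid_volume_L: float = Field(default=0.118, gt=0)
    tracer_no3: TracerDose = TracerDose(added_nmol=500.0, purity_fraction=0.99)
    tracer_nh4: TracerDose = TracerDose(added_nmol=80.0, purity_fraction=0.99)
    detection_limit_nmolN: float = Field(default=1.0, ge=0)
    no3_detection_umolL: float = Field(default=0.2, ge=0)
    nh4_detection_umolL: float = Field(default=0.015, ge=0)
    o2_threshold_uM: float = Field(default=1.0, gt=0)
    #: include the ambient substrate pool when computing f15 (if False, f15
    #: is simply the tracer purity)
    f15_includes_ambient: bool = True

    @model_validator(mode="after")
    def _check_ratios(self) -> "RunConfig":
        for name in ("r_ref", "r_air"):
            v = getattr(self, name)
            if not (0 < v < 0.05):
                raise ValueError(f"{name} must be in (0, 0.05), got {v}")
        return self

    @property
    def constants(self) -> IsotopeConstants:
        return IsotopeConstants(r_ref=self.r_ref, r_air=self.r_air)

    def dose_for(self, substrate: str) -> TracerDose:
        if substrate == "nitrate":
            return self.tracer_no3
        if substrate == "ammonium":
            return self.tracer_nh4
        raise ConfigError(f"unknown substrate {substrate!r}")


def load_config(path: str | Path | None) -> RunConfig:
    """Read a YAML config file; ``None`` returns all defaults."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        return RunConfig()
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} must contain a mapping")
    try:
        return RunConfig(**raw)
    except ValidationError as exc:
        raise ConfigError(f"invalid config {path}: {exc}") from exc
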