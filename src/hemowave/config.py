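"""Study configuration: a validated schema whose defaults reproduce the
reference experiment design exactly (2% BV / 5% LVC / 5% SVR steps;
pressure limits DBP 20, PP 20, MAP 30 mmHg; baroreflex recovery target
MAP 70 mmHg from an unstable MAP 60 mmHg with a 100% compensator cap;
spontaneous breathing at 11/min with 0.5 l tidal volume)."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

__all__ = ["StudyConfig", "Limits", "BaroreflexConfig", "BreathingConfig",
           "load_config", "save_config"]


class Limits(BaseModel):
    """Stop-rule pressure floors [mmHg]: a step is excluded once DBP or
    PP falls below 20 or MAP below 30."""
    model_config = ConfigDict(extra="forbid")
    dbp: float = Field(20.0, gt=0)
    pp: float = Field(20.0, gt=0)
    map: float = Field(30.0, gt=0)


class BaroreflexConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    enabled: bool = False
    age: int = 60
    compensators: list[str] = ["HR", "LVC", "SVR", "VC"]
    unstable_map: float = Field(60.0, gt=0, description="deficit starting point [mmHg]")
    recovery_map: float = Field(70.0, gt=0, description="recovery target [mmHg]")
    cap: float = Field(1.0, gt=0, le=1.0, description="max relative compensator change")
    substep: float = Field(0.02, gt=0, lt=1, description="compensator sub-step, fraction of baseline")


class BreathingConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    enabled: bool = True
    age: int = 60
    rate: float = Field(11.0, gt=0, description="breaths/min")
    tidal_volume: float = Field(0.5, gt=0, description="liter")
    duration_s: float = Field(60.0, ge=10)


class StudyConfig(BaseModel):
    """Full experiment grid: ages x causes reductions plus controls,
    optional baroreflex grid and the spontaneous-breathing run."""
    model_config = ConfigDict(extra="forbid")

    ages: list[int] = [20, 40, 60, 80]
    causes: list[str] = ["preload", "contractility", "afterload"]
    step_sizes: dict[str, float] = {"BV": 0.02, "LVC": 0.05, "SVR": 0.05}
    limits: Limits = Limits()
    baroreflex: BaroreflexConfig = BaroreflexConfig()
    breathing: BreathingConfig = BreathingConfig()
    step_duration_s: float = Field(15.0, ge=10)
    max_steps: int = Field(60, gt=0)
    normalized_samples: int = Field(200, ge=16, description="samples per normalized beat")

    @field_validator("causes")
    @classmethod
    def _known_causes(cls, v):
        known = {"preload", "contractility", "afterload"}
        bad = set(v) - known
        if bad:
            raise ValueError(f"unknown causes {sorted(bad)}; expected subset of {sorted(known)}")
        return v

    @field_validator("step_sizes")
    @classmethod
    def _steps_positive(cls, v):
        for k, s in v.items():
            if k not in {"BV", "LVC", "SVR"}:
                raise ValueError(f"unknown step-size key {k!r}")
            if not 0 < s < 1:
                raise ValueError(f"step size {k}={s} outside (0, 1)")
        return v


def load_config(path: str | Path | None = None) -> StudyConfig:
    """Load and validate a YAML config; an empty/missing file gives the
    full default design."""
    if path is None:
        return StudyConfig()
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        return StudyConfig()
    return StudyConfig.model_validate(data)


def save_config(config: StudyConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.model_dump(), sort_keys=False))
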