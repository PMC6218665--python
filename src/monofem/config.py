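"""Run-configuration schema: validated, strict, YAML round-trippable.

Every physical quantity carries the fixed unit system of the package
(mm, ms, mV; normalized amplitudes are 1/ms for volume and mm/ms for
surface stimuli).  Unknown keys are rejected so typos in parameter names
fail loudly before any computation.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = ["GeometryConfig", "ConductivityConfig", "IonicConfig", "TimeConfig",
           "StimulusConfig", "RunConfig", "load_config", "save_config"]

Vec3 = tuple[float, float, float]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeometryConfig(_Strict):
    dimensions: Vec3 = Field(description="box dimensions (Lx, Ly, Lz) in mm")
    h: float = Field(gt=0, description="target element size in mm")


class ConductivityConfig(_Strict):
    d_l: float = Field(gt=0, description="longitudinal normalized diffusivity, mm^2/ms")
    d_t: float = Field(gt=0, description="transverse normalized diffusivity, mm^2/ms")
    fiber: Vec3 = (1.0, 0.0, 0.0)

    @model_validator(mode="after")
    def _ordered(self):
        if self.d_l < self.d_t:
            raise ValueError("d_l must be >= d_t")
        return self


class IonicConfig(_Strict):
    alpha: float = 0.05
    c1: float = 52.0
    c2: float = 8.0
    mu1: float = 0.1
    mu2: float = 0.3
    b: float = 0.25
    gamma: float = 0.002
    Vr: float = -85.0
    Vp: float = 15.0
    r0: float = 0.1146
    time_scale: float = Field(default=1.0, gt=0,
                              description="ms per model time unit (12.9 = physiological)")

    @model_validator(mode="after")
    def _voltages(self):
        if self.Vp <= self.Vr:
            raise ValueError("Vp must exceed Vr")
        return self


class TimeConfig(_Strict):
    scheme: Literal["SI", "FI"] = "SI"
    dt: float = Field(gt=0, description="time step, ms")
    t_end: float = Field(gt=0, description="final time, ms")
    newton_tol: float = Field(default=1e-10, gt=0)
    newton_max_iter: int = Field(default=25, ge=1)
    snapshot_every_ms: Optional[float] = Field(default=None, gt=0)


class StimulusConfig(_Strict):
    kind: Literal["volume", "surface"]
    amplitude: float = Field(description="normalized: 1/ms (volume) or mm/ms (surface)")
    start: float = Field(ge=0, description="onset, ms")
    duration: float = Field(gt=0, description="duration, ms")
    box: Optional[tuple[tuple[float, float], tuple[float, float], tuple[float, float]]] = None
    face_set: Optional[str] = None

    @model_validator(mode="after")
    def _target(self):
        if self.kind == "volume" and self.box is None:
            raise ValueError("volume stimulus requires box")
        if self.kind == "surface" and self.face_set is None:
            raise ValueError("surface stimulus requires face_set")
        return self


class RunConfig(_Strict):
    name: str = "run"
    geometry: GeometryConfig
    family: Literal["Q1", "Q2", "Q1NC"] = "Q1"
    conductivity: ConductivityConfig
    ionic: IonicConfig = IonicConfig()
    time: TimeConfig
    stimuli: list[StimulusConfig] = []
    probes: list[Vec3] = []
    threshold: float = 0.5
    stop_when: Literal["t_end", "probes_activated", "all_activated"] = "t_end"


def load_config(path) -> RunConfig:
    """Read and validate a YAML run configuration."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return RunConfig.model_validate(data)


def save_config(cfg: RunConfig, path) -> None:
    """Serialize a run configuration to YAML (round-trips exactly)."""
    Path(path).write_text(yaml.safe_dump(cfg.model_dump(mode="json"), sort_keys=False))
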