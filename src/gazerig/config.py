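"""Run configuration: one serializable object defining a full run.

Defaults reproduce the reference rig: 927 mm viewing distance on a
531.36 x 298.89 mm, 1920 x 1080 screen; 1.8° steppers in 16x
microstepping at 3200 pps with an 80,000 pps^2 ramp; three brightness
conditions that never alter the motion.  ``load``/``save`` round-trip
through JSON losslessly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

from pydantic import BaseModel, Field

from .geometry import CameraGeometry, ScreenGeometry
from .rig import (
    DEFAULT_NOISE_SD_DEG,
    DEFAULT_PUPIL_BASE_AU,
    DEFAULT_PUPIL_NOISE_AU,
    MotorConfig,
)

__all__ = ["RunConfig"]


class ScreenModel(BaseModel):
    width_mm: float = 531.36
    height_mm: float = 298.89
    width_px: int = 1920
    height_px: int = 1080
    viewing_distance_mm: float = 927.0

    def build(self) -> ScreenGeometry:
        return ScreenGeometry(**self.model_dump())


class CameraModel(BaseModel):
    offset_mm: tuple[float, float, float] = (-100.0, 120.0, 530.0)
    eye_height_mm: float = 290.0

    def build(self) -> CameraGeometry:
        return CameraGeometry(**self.model_dump())


class MotorModel(BaseModel):
    full_step_deg: float = 1.8
    microstep_factor: int = 16
    v_max_pps: float = 3200.0
    accel_pps2: float = 80_000.0
    quant_error_microsteps: int = 2
    backlash_deg: tuple[float, float] = (0.0, 0.0)

    def build(self) -> MotorConfig:
        return MotorConfig(**self.model_dump())


class RunConfig(BaseModel):
    """Everything that determines a run's outputs, bit for bit."""

    screen: ScreenModel = Field(default_factory=ScreenModel)
    camera: CameraModel = Field(default_factory=CameraModel)
    motor: MotorModel = Field(default_factory=MotorModel)
    conditions: tuple[str, ...] = ("dark", "medium", "light")
    noise_sd_deg: float = DEFAULT_NOISE_SD_DEG
    pupil_base_au: float = DEFAULT_PUPIL_BASE_AU
    pupil_noise_au: float = DEFAULT_PUPIL_NOISE_AU
    n_participants: int = 20
    n_saccades: int = 50
    n_trials: int = 100
    fixation_ms: int = 300
    seed: int = 0

    def save(self, path) -> None:
        Path(path).write_text(self.model_dump_json(indent=1))

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.model_validate_json(Path(path).read_text())

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.model_dump(), sort_keys=True, default=list).encode()
        ).hexdigest()[:16]
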