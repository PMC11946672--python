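"""Coordinate, angle, luminance-contrast and projection arithmetic.

Everything downstream — the rig simulator as much as the analysis chain —
shares the conversions in this module, so the forward model (gimbal angles
to screen pixels) and the metrics (pixel deviations to degrees of visual
angle) are guaranteed to use the same geometry.

Conventions
-----------
* Screen coordinates are 0-based pixels, origin top-left, x rightward,
  y downward; the screen centre of the default 1920x1080 monitor is
  (960, 540).
* Visual angles are computed per axis as ``atan(offset_mm / distance_mm)``
  of the linear offset from the screen centre, with the eye on the
  screen-centre normal.  Positive angles point right (x) and down (y),
  matching screen coordinates.
* The pixel pitch is taken from the horizontal dimension and applied to
  both axes; the monitor modelled here has square pixels (531.36/1920 and
  298.89/1080 agree to 4 decimals).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "ScreenGeometry",
    "CameraGeometry",
    "LaserRig",
    "BrightnessCondition",
    "DEFAULT_CONDITIONS",
    "px_to_mm",
    "mm_to_deg",
    "px_to_deg",
    "deg_to_px",
    "weber_contrast",
    "microstep_resolution",
    "pps_to_dps",
    "positioning_error",
    "laser_displacement",
    "gaze_unit_vector",
    "apparent_pupil_area",
    "target_to_gaze_angles",
    "gaze_angles_to_px",
]


@dataclass(frozen=True)
class ScreenGeometry:
    """Physical and pixel dimensions of the stimulus display.

    Defaults describe a 24-inch 1920x1080 monitor (531.36 x 298.89 mm)
    viewed from 927 mm.
    """

    width_mm: float = 531.36
    height_mm: float = 298.89
    width_px: int = 1920
    height_px: int = 1080
    viewing_distance_mm: float = 927.0

    def __post_init__(self) -> None:
        for name in ("width_mm", "height_mm", "width_px", "height_px", "viewing_distance_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if abs(self.width_mm / self.width_px - self.height_mm / self.height_px) > 1e-4:
            raise ValueError("non-square pixels: horizontal and vertical pitch disagree")

    @property
    def pitch_mm(self) -> float:
        """Pixel pitch in mm/px (horizontal; pixels are square)."""
        return self.width_mm / self.width_px

    @property
    def center_px(self) -> tuple[float, float]:
        return (self.width_px / 2.0, self.height_px / 2.0)


@dataclass(frozen=True)
class CameraGeometry:
    """Position of the tracker camera lens relative to the eye centre.

    ``offset_mm`` is the eye-to-lens vector in the screen frame: x rightward,
    y downward, z from the eye toward the screen.  The default places the
    lens left of and below the eye, in front of it — the typical
    desktop-tracker arrangement below the stimulus monitor.  For the
    left/down pupil bias to dominate the cosine foreshortening model, the
    camera's angular offset per axis must exceed half the eccentricity of
    the outermost gaze targets; the default azimuth (10.7° left) and
    elevation (12.8° down) both do for the 14.2° calibration grid.
    """

    offset_mm: tuple[float, float, float] = (-100.0, 120.0, 530.0)
    eye_height_mm: float = 290.0

    def __post_init__(self) -> None:
        if self.offset_mm[2] <= 0:
            raise ValueError("camera must sit in front of the eye (positive z offset)")

    @property
    def direction(self) -> np.ndarray:
        """Unit vector from the eye centre to the camera lens."""
        v = np.asarray(self.offset_mm, dtype=float)
        return v / np.linalg.norm(v)


@dataclass(frozen=True)
class LaserRig:
    """Laser-and-mirror projection rig: a canvas facing the eye, with the
    laser source at its centre aimed at a front-surface mirror on the eye."""

    canvas_distance_mm: float = 700.0
    canvas_width_mm: float = 679.0
    canvas_height_mm: float = 498.0
    step_deg: float = 0.9

    def __post_init__(self) -> None:
        for name in ("canvas_distance_mm", "canvas_width_mm", "canvas_height_mm", "step_deg"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class BrightnessCondition:
    """One display illumination condition: background/target RGB and
    luminance, with the derived Weber contrast."""

    name: str
    bg_rgb: tuple[int, int, int]
    target_rgb: tuple[int, int, int]
    L_bg: float
    L_target: float
    C_W: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "C_W", weber_contrast(self.L_bg, self.L_target))


def px_to_mm(offset_px, screen: ScreenGeometry = ScreenGeometry()):
    """Convert a signed pixel offset to millimetres on the screen surface."""
    return np.asarray(offset_px, dtype=float) * screen.pitch_mm if np.ndim(offset_px) else float(offset_px) * screen.pitch_mm


def mm_to_deg(offset_mm, distance_mm: float):
    """Convert a signed linear offset at ``distance_mm`` to degrees of
    visual angle (``atan`` of the ratio; odd and monotone)."""
    if distance_mm <= 0:
        raise ValueError("distance_mm must be positive")
    return np.degrees(np.arctan(np.asarray(offset_mm, dtype=float) / distance_mm)) if np.ndim(offset_mm) else math.degrees(math.atan(offset_mm / distance_mm))


def px_to_deg(offset_px, screen: ScreenGeometry = ScreenGeometry()):
    """Signed pixel offset from centre to degrees of visual angle."""
    return mm_to_deg(px_to_mm(offset_px, screen), screen.viewing_distance_mm)


def deg_to_px(angle_deg, screen: ScreenGeometry = ScreenGeometry()):
    """Inverse of :func:`px_to_deg`: degrees to signed pixel offset."""
    mm = np.tan(np.radians(np.asarray(angle_deg, dtype=float))) * screen.viewing_distance_mm
    out = mm / screen.pitch_mm
    return out if np.ndim(angle_deg) else float(out)


def weber_contrast(L_bg: float, L_target: float) -> float:
    """Weber contrast (L_bg - L_target)/L_bg of a target on a background."""
    if L_bg <= 0:
        raise ValueError("background luminance must be positive")
    return (L_bg - L_target) / L_bg


def microstep_resolution(full_step_deg: float = 1.8, microstep_factor: int = 16) -> float:
    """Angular resolution per microstep; 1.8°/16 = 0.1125° by default."""
    if full_step_deg <= 0 or microstep_factor <= 0:
        raise ValueError("full_step_deg and microstep_factor must be positive")
    return full_step_deg / microstep_factor


def pps_to_dps(pulses_per_second: float, resolution_deg: float) -> float:
    """Stepper pulse rate (one pulse = one microstep) to angular speed."""
    return pulses_per_second * resolution_deg


def positioning_error(n_microsteps: float, resolution_deg: float) -> float:
    """Worst-case positioning error of ``n_microsteps`` at the given
    resolution; the rig's estimated bound is 2 x 0.1125° = 0.225°."""
    if n_microsteps < 0:
        raise ValueError("n_microsteps must be non-negative")
    return n_microsteps * resolution_deg


def laser_displacement(
    eye_angle_deg: float,
    rig: LaserRig = LaserRig(),
    model: Literal["doubled_tangent", "specular"] = "doubled_tangent",
) -> float:
    """Displacement of the reflected laser spot on the canvas for an eye
    rotation of ``eye_angle_deg``.

    A mirror mounted perpendicular to the viewing direction deflects the
    reflected ray by twice the eye rotation.  ``doubled_tangent`` applies
    the doubling to the tangent displacement, ``2 D tan(theta)`` — the
    convention used in the rig's published planning arithmetic (15 steps of
    0.9° at 700 mm give 33.6 cm).  ``specular`` is the exact ray-optics
    alternative ``D tan(2 theta)`` (35.7 cm for the same rotation).
    """
    if abs(eye_angle_deg) >= 45.0:
        raise ValueError("eye rotation out of range (|angle| must be < 45°)")
    th = math.radians(eye_angle_deg)
    if model == "doubled_tangent":
        return 2.0 * rig.canvas_distance_mm * math.tan(th)
    if model == "specular":
        return rig.canvas_distance_mm * math.tan(2.0 * th)
    raise ValueError(f"unknown laser model {model!r}")


#: The three measured illumination conditions of the default setup
#: (grey-on-grey dots, Weber contrasts 0.68 / 0.85 / 0.83).
DEFAULT_CONDITIONS: tuple[BrightnessCondition, ...] = (
    BrightnessCondition("dark", (20, 20, 20), (0, 0, 0), 2.74, 0.89),
    BrightnessCondition("medium", (100, 100, 100), (43, 43, 43), 47.09, 6.83),
    BrightnessCondition("light", (240, 240, 240), (95, 95, 95), 232.03, 40.24),
)


def gaze_unit_vector(theta_x_deg, theta_y_deg) -> np.ndarray:
    """Unit gaze vector(s) for per-axis visual angles (x right, y down,
    z toward the screen).  Accepts scalars or equal-length arrays and
    returns shape (3,) or (n, 3)."""
    tx = np.tan(np.radians(np.asarray(theta_x_deg, dtype=float)))
    ty = np.tan(np.radians(np.asarray(theta_y_deg, dtype=float)))
    v = np.stack([tx, ty, np.ones_like(tx)], axis=-1)
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


def apparent_pupil_area(gaze_dir, camera: CameraGeometry, base_area: float):
    """Apparent (imaged) pupil area for a given gaze direction.

    The rigid circular pupil of radius r presents, to a camera off the gaze
    axis by angle gamma, an ellipse of area ``pi r^2 cos(gamma)`` — the
    foreshortening that biases video pupillometry.  ``gaze_dir`` may be a
    single unit 3-vector or an (n, 3) array; gamma is the angle between the
    gaze direction and the eye-to-camera direction.  Beyond 90° the pupil
    faces away from the camera and the area is clipped to zero.
    """
    if base_area <= 0:
        raise ValueError("base_area must be positive")
    g = np.asarray(gaze_dir, dtype=float)
    cos_gamma = g @ camera.direction
    out = base_area * np.clip(cos_gamma, 0.0, None)
    return out if g.ndim > 1 else float(out)


def target_to_gaze_angles(target_px, screen: ScreenGeometry = ScreenGeometry()):
    """Gaze angles (theta_x, theta_y) in degrees that fixate a screen
    coordinate, for an eye on the screen-centre normal.

    Inverse of :func:`gaze_angles_to_px` to numerical precision.  Targets
    outside the screen are still computed (the rig can be commanded past
    the screen edge); no clipping is applied.
    """
    t = np.asarray(target_px, dtype=float)
    cx, cy = screen.center_px
    th_x = px_to_deg(t[..., 0] - cx, screen)
    th_y = px_to_deg(t[..., 1] - cy, screen)
    return th_x, th_y


def gaze_angles_to_px(theta_x_deg, theta_y_deg, screen: ScreenGeometry = ScreenGeometry()):
    """Forward projection of gaze angles onto the screen, in pixels."""
    cx, cy = screen.center_px
    return deg_to_px(theta_x_deg, screen) + cx, deg_to_px(theta_y_deg, screen) + cy
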