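"""Digital twin of the two-axis stepper gimbal driving an artificial eye.

The simulated rig reproduces the kinematics of a microstepped stepper pair
moving a rigid eye prop: trapezoidal velocity profiles with a hard
acceleration and speed ceiling, a microstep position lattice with a small
random positioning error, simultaneous (superposed) motion of both axes,
and 300 ms fixations between target jumps.  On top of the deterministic
motion a tracker model adds Gaussian position noise and an apparent pupil
area that depends on gaze direction only — by construction the display
brightness condition never alters the motion (the null model under test).

All randomness flows from :class:`numpy.random.SeedSequence`, so a dataset
regenerates bit-identically from its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .geometry import (
    CameraGeometry,
    ScreenGeometry,
    apparent_pupil_area,
    deg_to_px,
    gaze_angles_to_px,
    gaze_unit_vector,
    microstep_resolution,
    pps_to_dps,
    target_to_gaze_angles,
)

__all__ = [
    "MotorConfig",
    "Pattern",
    "TrialPlan",
    "SampleStream",
    "CALIBRATION_GRID_13",
    "DEFAULT_NOISE_SD_DEG",
    "DEFAULT_PUPIL_BASE_AU",
    "DEFAULT_PUPIL_NOISE_AU",
    "plan_calibration_grid",
    "plan_line_pattern",
    "plan_random_saccades",
    "motor_move_profile",
    "superpose_axes",
    "simulate_trial",
    "simulate_experiment",
]

#: Default tracker position noise, degrees of visual angle (SD per axis).
DEFAULT_NOISE_SD_DEG = 0.02
#: Default base pupil area in tracker arbitrary units; calibrated so the
#: grand-mean area corresponds to the 5 mm artificial pupil.
DEFAULT_PUPIL_BASE_AU = 2888.94
#: Default additive pupil measurement noise (a.u., SD).
DEFAULT_PUPIL_NOISE_AU = 10.0


@dataclass(frozen=True)
class MotorConfig:
    """Kinematic constants of the stepper drive.

    The defaults are 1.8° NEMA-17 motors in 16x microstepping mode driven
    at up to 3200 pulses/s with an 80,000 pulse/s^2 ramp: a 0.1125°
    microstep lattice, a 360°/s speed ceiling and a 9000°/s^2 acceleration
    ceiling.  ``quant_error_microsteps`` is the worst-case positioning
    error of the drive train (+-2 microsteps = +-0.225°).
    """

    full_step_deg: float = 1.8
    microstep_factor: int = 16
    v_max_pps: float = 3200.0
    accel_pps2: float = 80_000.0
    quant_error_microsteps: int = 2
    backlash_deg: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if min(self.full_step_deg, self.microstep_factor, self.v_max_pps, self.accel_pps2) <= 0:
            raise ValueError("motor constants must be strictly positive")
        if self.quant_error_microsteps < 0:
            raise ValueError("quant_error_microsteps must be >= 0")

    @property
    def resolution_deg(self) -> float:
        return microstep_resolution(self.full_step_deg, self.microstep_factor)

    @property
    def v_max_dps(self) -> float:
        return pps_to_dps(self.v_max_pps, self.resolution_deg)

    @property
    def accel_dps2(self) -> float:
        return pps_to_dps(self.accel_pps2, self.resolution_deg)

    @property
    def critical_amplitude_deg(self) -> float:
        """Amplitude v^2/a below which a move never reaches full speed
        (triangular profile); 14.4° at the defaults."""
        return self.v_max_dps**2 / self.accel_dps2


@dataclass(frozen=True)
class Pattern:
    """An ordered list of screen targets, e.g. a calibration grid."""

    name: str
    targets: np.ndarray  # (n, 2) pixels

    def __post_init__(self) -> None:
        t = np.asarray(self.targets, dtype=float).reshape(-1, 2)
        object.__setattr__(self, "targets", t)


@dataclass(frozen=True)
class TrialPlan:
    """Targets for one simulated participant under one condition."""

    participant_id: int
    condition: str
    targets: np.ndarray  # (n, 2) pixels
    fixation_ms: int = 300
    seed: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "targets", np.asarray(self.targets, dtype=float).reshape(-1, 2))


@dataclass
class SampleStream:
    """A 1 kHz gaze recording: time, screen position, apparent pupil area.

    ``meta`` carries everything needed to regenerate or interpret the
    stream: the plan, ground-truth move/fixation segments and the seeds.
    """

    t_ms: np.ndarray
    x_px: np.ndarray
    y_px: np.ndarray
    pupil_au: np.ndarray
    fs_hz: int = 1000
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return self.t_ms.size

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"t_ms": self.t_ms, "x_px": self.x_px, "y_px": self.y_px, "pupil_au": self.pupil_au}
        )


# 13-point calibration grid of the default 1920x1080 screen: centre,
# vertical extremes, horizontal extremes, outer corners, inner diamond.
CALIBRATION_GRID_13 = np.array(
    [
        (960, 540),
        (960, 92),
        (960, 988),
        (115, 540),
        (1805, 540),
        (115, 92),
        (1805, 92),
        (115, 988),
        (1805, 988),
        (538, 316),
        (1382, 316),
        (538, 764),
        (1382, 764),
    ],
    dtype=float,
)


def plan_calibration_grid(screen: ScreenGeometry = ScreenGeometry()) -> Pattern:
    """The 13-point calibration grid pattern for the default screen."""
    if (screen.width_px, screen.height_px) != (1920, 1080):
        raise ValueError("the 13-point grid is defined for the 1920x1080 screen")
    return Pattern("grid13", CALIBRATION_GRID_13.copy())


def plan_line_pattern(
    axis: str = "h",
    n_points: int = 7,
    screen: ScreenGeometry = ScreenGeometry(),
    margin_frac: float = 0.10,
) -> Pattern:
    """A single horizontal or vertical line of equally spaced targets
    through the screen centre."""
    cx, cy = screen.center_px
    if axis == "h":
        xs = np.linspace(screen.width_px * margin_frac, screen.width_px * (1 - margin_frac), n_points)
        pts = np.column_stack([xs, np.full(n_points, cy)])
        return Pattern("h_line", pts)
    if axis == "v":
        ys = np.linspace(screen.height_px * margin_frac, screen.height_px * (1 - margin_frac), n_points)
        pts = np.column_stack([np.full(n_points, cx), ys])
        return Pattern("v_line", pts)
    raise ValueError("axis must be 'h' or 'v'")


def plan_random_saccades(
    n: int,
    amp_range_deg: tuple[float, float] = (4.5, 14.1),
    margin_frac: float = 0.10,
    seed=None,
    screen: ScreenGeometry = ScreenGeometry(),
    max_tries: int = 2000,
) -> np.ndarray:
    """Randomly placed targets yielding ``n`` saccades of amplitude within
    ``amp_range_deg`` in uniformly random directions.

    Targets are constrained to the screen shrunk by ``margin_frac`` per
    side so overshoot cannot leave the trackable area.  Amplitude is the
    Euclidean norm of the per-axis visual-angle displacement; direction is
    uniform on the circle, length uniform in the stated range.  Returns an
    ``(n + 1, 2)`` pixel array.  Deterministic given ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = amp_range_deg
    if not (0 < lo <= hi):
        raise ValueError("invalid amplitude range")
    rng = np.random.default_rng(seed)
    x0, x1 = screen.width_px * margin_frac, screen.width_px * (1 - margin_frac)
    y0, y1 = screen.height_px * margin_frac, screen.height_px * (1 - margin_frac)

    pts = np.empty((n + 1, 2))
    pts[0] = (rng.uniform(x0, x1), rng.uniform(y0, y1))
    for i in range(1, n + 1):
        thx, thy = target_to_gaze_angles(pts[i - 1], screen)
        for _ in range(max_tries):
            amp = rng.uniform(lo, hi)
            phi = rng.uniform(0.0, 2.0 * math.pi)
            nx, ny = gaze_angles_to_px(thx + amp * math.cos(phi), thy + amp * math.sin(phi), screen)
            if x0 <= nx <= x1 and y0 <= ny <= y1:
                pts[i] = (nx, ny)
                break
        else:
            raise RuntimeError(
                f"could not place target {i}: amplitude range {amp_range_deg} "
                f"infeasible within the {margin_frac:.0%} margin box"
            )
    return pts


def motor_move_profile(delta_deg: float, cfg: MotorConfig = MotorConfig(), fs_hz: int = 1000) -> np.ndarray:
    """Angular position of one axis during a point-to-point move, sampled
    on the 1 kHz clock.

    The drive ramps at ``accel_dps2`` to at most ``v_max_dps`` and ramps
    down symmetrically: a trapezoidal velocity profile, degenerating to a
    triangle for moves shorter than v^2/a (14.4° at the defaults, with
    peak speed sqrt(a*d)).  The commanded displacement is first quantized
    to the microstep lattice.  Returns positions at t = 1..T ms relative
    to the start (the sample at t = 0 is the pre-move position and is not
    included); the final sample equals the quantized displacement exactly.
    """
    res = cfg.resolution_deg
    delta_q = round(delta_deg / res) * res
    if delta_q == 0.0:
        return np.empty(0)
    d = abs(delta_q)
    s = math.copysign(1.0, delta_q)
    a = cfg.accel_dps2
    v = cfg.v_max_dps
    if d >= cfg.critical_amplitude_deg:
        t_acc = v / a
        t_plateau = (d - v * t_acc) / v
        v_pk = v
    else:
        t_acc = math.sqrt(d / a)
        t_plateau = 0.0
        v_pk = a * t_acc
    T = 2.0 * t_acc + t_plateau
    n = max(1, math.ceil(T * fs_hz))
    t = np.arange(1, n + 1) / fs_hz
    pos = np.empty(n)
    m_acc = t <= t_acc
    m_pl = (t > t_acc) & (t <= t_acc + t_plateau)
    m_dec = t > t_acc + t_plateau
    pos[m_acc] = 0.5 * a * t[m_acc] ** 2
    pos[m_pl] = 0.5 * a * t_acc**2 + v_pk * (t[m_pl] - t_acc)
    td = np.minimum(T - t[m_dec], t_acc)
    pos[m_dec] = d - 0.5 * a * td**2
    pos[-1] = d
    return s * pos


def superpose_axes(x_traj: np.ndarray, y_traj: np.ndarray) -> np.ndarray:
    """Combine two per-axis move trajectories on a common clock.

    The orthogonal hinge superposes the axes without mutual influence; the
    shorter trajectory is padded with its terminal value.  Returns an
    (n, 2) array of (theta_x, theta_y) relative to the move start.
    """
    n = max(x_traj.size, y_traj.size)
    out = np.zeros((n, 2))
    out[: x_traj.size, 0] = x_traj
    if x_traj.size and x_traj.size < n:
        out[x_traj.size :, 0] = x_traj[-1]
    out[: y_traj.size, 1] = y_traj
    if y_traj.size and y_traj.size < n:
        out[y_traj.size :, 1] = y_traj[-1]
    return out


def _quantized_target_angles(
    targets_px: np.ndarray,
    cfg: MotorConfig,
    screen: ScreenGeometry,
    rng: np.random.Generator,
) -> np.ndarray:
    """Map planned screen targets to the motor angles actually reached:
    quantized to the microstep lattice plus an integer positioning error
    uniform in [-q, +q] microsteps per axis and visit."""
    res = cfg.resolution_deg
    thx, thy = target_to_gaze_angles(targets_px, screen)
    ang = np.column_stack([thx, thy])
    steps = np.round(ang / res)
    q = cfg.quant_error_microsteps
    if q > 0:
        steps += rng.integers(-q, q + 1, size=steps.shape)
    return steps * res


def simulate_trial(
    plan: TrialPlan,
    cfg: MotorConfig = MotorConfig(),
    screen: ScreenGeometry = ScreenGeometry(),
    camera: CameraGeometry = CameraGeometry(),
    noise_sd_deg: float = DEFAULT_NOISE_SD_DEG,
    pupil_base_au: float = DEFAULT_PUPIL_BASE_AU,
    pupil_noise_au: float = DEFAULT_PUPIL_NOISE_AU,
    motion_seed=None,
    noise_seed=None,
    transition_from_px: tuple[float, float] | None = None,
) -> SampleStream:
    """Simulate one recording: the rig visits ``plan.targets`` in order,
    fixating ``fixation_ms`` at each, and the tracker model renders 1 kHz
    samples.

    ``motion_seed`` drives the motor positioning errors (and must be shared
    across brightness conditions of one participant for the null model);
    ``noise_seed`` drives the tracker measurement noise.  If
    ``transition_from_px`` is given, the recording starts with a flagged
    transition move from that position to the first target (mimicking the
    oversized jumps between consecutive participants); ``meta["transition_end_ms"]``
    marks its end.
    """
    if noise_sd_deg < 0:
        raise ValueError("noise_sd_deg must be >= 0")
    m_rng = np.random.default_rng(motion_seed)
    n_rng = np.random.default_rng(noise_seed)

    targets = plan.targets
    angles = _quantized_target_angles(targets, cfg, screen, m_rng)

    chunks: list[np.ndarray] = []
    fix_segments: list[tuple[int, int, int]] = []  # (start_ms, end_ms, target_idx), end exclusive
    move_segments: list[tuple[int, int, int]] = []  # (start_ms, end_ms, to_target_idx)
    t = 0
    transition_end_ms = 0

    if transition_from_px is not None:
        thx0, thy0 = target_to_gaze_angles(np.asarray(transition_from_px, float), screen)
        start = np.array([round(thx0 / cfg.resolution_deg), round(thy0 / cfg.resolution_deg)]) * cfg.resolution_deg
        chunks.append(np.repeat(start[None, :], 50, axis=0))  # brief settle at the old position
        t += 50
        mv = superpose_axes(
            motor_move_profile(angles[0, 0] - start[0], cfg),
            motor_move_profile(angles[0, 1] - start[1], cfg),
        )
        chunks.append(start + mv)
        move_segments.append((t, t + len(mv), -1))
        t += len(mv)
        transition_end_ms = t

    for i in range(len(targets)):
        fix = np.repeat(angles[i][None, :], plan.fixation_ms, axis=0)
        chunks.append(fix)
        fix_segments.append((t, t + plan.fixation_ms, i))
        t += plan.fixation_ms
        if i + 1 < len(targets):
            mv = superpose_axes(
                motor_move_profile(angles[i + 1, 0] - angles[i, 0], cfg),
                motor_move_profile(angles[i + 1, 1] - angles[i, 1], cfg),
            )
            chunks.append(angles[i] + mv)
            move_segments.append((t, t + len(mv), i + 1))
            t += len(mv)

    traj = np.vstack(chunks)
    n = len(traj)

    x_px, y_px = gaze_angles_to_px(traj[:, 0], traj[:, 1], screen)
    if noise_sd_deg > 0:
        sd_px = deg_to_px(noise_sd_deg, screen)
        x_px = x_px + n_rng.normal(0.0, sd_px, n)
        y_px = y_px + n_rng.normal(0.0, sd_px, n)
    pupil = apparent_pupil_area(gaze_unit_vector(traj[:, 0], traj[:, 1]), camera, pupil_base_au)
    if pupil_noise_au > 0:
        pupil = pupil + n_rng.normal(0.0, pupil_noise_au, n)

    return SampleStream(
        t_ms=np.arange(n, dtype=np.int64),
        x_px=np.asarray(x_px, float),
        y_px=np.asarray(y_px, float),
        pupil_au=np.asarray(pupil, float),
        meta={
            "participant": plan.participant_id,
            "condition": plan.condition,
            "targets_px": targets,
            "fixation_ms": plan.fixation_ms,
            "fix_segments": fix_segments,
            "move_segments": move_segments,
            "transition_end_ms": transition_end_ms,
            "noise_sd_deg": noise_sd_deg,
            "pupil_base_au": pupil_base_au,
            "pupil_noise_au": pupil_noise_au,
        },
    )


def simulate_experiment(
    n_participants: int = 200,
    n_saccades: int = 200,
    conditions: Sequence[str] = ("dark", "medium", "light"),
    seed=None,
    shared_noise: bool = False,
    with_transitions: bool = True,
    **trial_kwargs,
) -> Iterator[SampleStream]:
    """Generate the full brightness experiment as a stream iterator.

    Each participant gets one random saccade plan reused verbatim across
    all brightness conditions, and the motor positioning errors are
    likewise condition-independent: the motion is identical across
    conditions by construction, so brightness is a pure label (the null
    model).  Tracker measurement noise is drawn independently per
    condition unless ``shared_noise`` is set, in which case the streams of
    one participant are bit-identical across conditions.

    Yields ``n_participants * len(conditions)`` streams; the planned
    saccade count is ``n_participants * n_saccades * len(conditions)``.
    """
    if min(n_participants, n_saccades, len(conditions)) < 1:
        raise ValueError("all experiment sizes must be >= 1")
    screen = trial_kwargs.get("screen", ScreenGeometry())
    ss = np.random.SeedSequence(seed)
    part_seeds = ss.spawn(n_participants)
    prev_last: tuple[float, float] | None = None
    for p, pseed in enumerate(part_seeds):
        plan_ss, motion_ss, noise_root = pseed.spawn(3)
        targets = plan_random_saccades(n_saccades, seed=plan_ss, screen=screen)
        noise_seeds = noise_root.spawn(1 if shared_noise else len(conditions))
        for ci, cond in enumerate(conditions):
            plan = TrialPlan(participant_id=p, condition=cond, targets=targets)
            yield simulate_trial(
                plan,
                motion_seed=motion_ss,
                noise_seed=noise_seeds[0 if shared_noise else ci],
                transition_from_px=prev_last if with_transitions else None,
                **trial_kwargs,
            )
        prev_last = tuple(targets[-1])
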