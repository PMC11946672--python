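"""Event extraction from gaze sample streams.

Velocity is the first derivative of position (converted to degrees of
visual angle first) from a 3rd-order Savitzky-Golay filter with a
seven-sample window.  Saccades are velocity outliers: at least six
consecutive samples whose combined speed exceeds an adaptive threshold
eta = lambda * sigma (lambda = 3), where sigma is the velocity noise
level estimated per axis by an iterative data-driven scheme.  Fixation
windows are the stretches between saccades, trimmed by a guard interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .geometry import ScreenGeometry, px_to_deg
from .rig import SampleStream

__all__ = [
    "VelocitySignal",
    "NoiseEstimate",
    "SaccadeEvent",
    "FixationWindow",
    "sg_velocity",
    "estimate_noise_sigma",
    "detect_saccades",
    "saccade_metrics",
    "extract_fixations",
]


@dataclass
class VelocitySignal:
    """Per-axis angular velocity and combined speed, deg/s, on the
    stream's 1 ms clock."""

    t_ms: np.ndarray
    vx: np.ndarray
    vy: np.ndarray

    @property
    def v(self) -> np.ndarray:
        return np.hypot(self.vx, self.vy)


@dataclass(frozen=True)
class NoiseEstimate:
    """Estimated velocity-noise level per axis and the derived saccade
    threshold eta = lambda * sigma."""

    sigma_x: float
    sigma_y: float
    lam: float = 3.0
    iterations: int = 0

    @property
    def eta_x(self) -> float:
        return self.lam * self.sigma_x

    @property
    def eta_y(self) -> float:
        return self.lam * self.sigma_y

    @property
    def eta(self) -> float:
        """Threshold applied to the combined speed (the larger per-axis eta)."""
        return self.lam * max(self.sigma_x, self.sigma_y)


@dataclass
class SaccadeEvent:
    """One detected saccade: a maximal supra-threshold run of samples."""

    onset_ms: int
    offset_ms: int  # inclusive index of the last supra-threshold sample
    amplitude_deg: float = float("nan")
    peak_velocity_dps: float = float("nan")
    direction_deg: float = float("nan")
    participant: int | None = None
    condition: str | None = None
    is_transition: bool = False
    is_fragment: bool = False

    @property
    def duration_ms(self) -> int:
        return self.offset_ms - self.onset_ms + 1


@dataclass
class FixationWindow:
    """Samples attributed to one planned target, with summary statistics."""

    target_index: int
    planned_px: tuple[float, float]
    start_ms: int
    end_ms: int  # exclusive
    mean_x: float
    mean_y: float
    sd_x: float
    sd_y: float
    mean_pupil_au: float
    n_samples: int


def sg_velocity(stream: SampleStream, order: int = 3, window: int = 7,
                screen: ScreenGeometry = ScreenGeometry()) -> VelocitySignal:
    """Savitzky-Golay first-derivative velocity of a gaze stream, deg/s.

    Positions are converted from pixels to degrees of visual angle about
    the screen centre before differentiation, so thresholds and peak
    velocities are in deg/s.
    """
    if len(stream) < window:
        raise ValueError(f"stream of {len(stream)} samples shorter than the {window}-sample window")
    dt_s = 1.0 / stream.fs_hz
    cx, cy = screen.center_px
    theta_x = px_to_deg(stream.x_px - cx, screen)
    theta_y = px_to_deg(stream.y_px - cy, screen)
    vx = savgol_filter(theta_x, window, order, deriv=1, delta=dt_s)
    vy = savgol_filter(theta_y, window, order, deriv=1, delta=dt_s)
    return VelocitySignal(t_ms=stream.t_ms, vx=vx, vy=vy)


def _iterate_sigma(v_abs: np.ndarray, start_threshold: float, tol: float, max_iter: int) -> tuple[float, int]:
    T = start_threshold
    sigma = max(float(np.std(v_abs[v_abs < T])) if np.any(v_abs < T) else 0.0, 1e-6)
    it = 0
    for it in range(1, max_iter + 1):
        below = v_abs < T
        if not np.any(below):
            break
        sub = v_abs[below]
        sigma = max(float(np.std(sub)), 1e-6)
        T_new = float(np.mean(sub)) + 6.0 * sigma
        if abs(T_new - T) < tol:
            T = T_new
            break
        T = T_new
    return sigma, it


def estimate_noise_sigma(velocity: VelocitySignal, start_threshold_dps: float = 100.0,
                         lam: float = 3.0, tol_dps: float = 1.0, max_iter: int = 100) -> NoiseEstimate:
    """Data-driven estimate of the velocity noise level per axis.

    Starting from a generous threshold, sigma is the SD of the
    sub-threshold |velocity| samples and the threshold is updated to
    mean + 6*sigma of those samples, iterating until it moves by less
    than ``tol_dps``.  Saccade peaks, being sparse and far above the
    updated threshold, barely perturb the estimate.  An all-zero signal
    yields the floor sigma = 1e-6 deg/s rather than a zero threshold.
    """
    if velocity.t_ms.size == 0:
        raise ValueError("empty velocity signal")
    sx, itx = _iterate_sigma(np.abs(velocity.vx), start_threshold_dps, tol_dps, max_iter)
    sy, ity = _iterate_sigma(np.abs(velocity.vy), start_threshold_dps, tol_dps, max_iter)
    return NoiseEstimate(sigma_x=sx, sigma_y=sy, lam=lam, iterations=max(itx, ity))


def _supra_runs(above: np.ndarray, min_run: int) -> list[tuple[int, int]]:
    """Maximal runs of True of length >= min_run, as (start, stop-exclusive)."""
    if above.size == 0:
        return []
    padded = np.diff(np.concatenate(([0], above.view(np.int8), [0])))
    starts = np.flatnonzero(padded == 1)
    stops = np.flatnonzero(padded == -1)
    return [(int(a), int(b)) for a, b in zip(starts, stops) if b - a >= min_run]


def detect_saccades(velocity: VelocitySignal, noise: NoiseEstimate, min_run: int = 6) -> list[SaccadeEvent]:
    """Velocity-outlier saccade detection.

    A saccade is a maximal run of at least ``min_run`` consecutive samples
    whose combined speed exceeds the adaptive threshold ``noise.eta``.
    Events are returned time-ordered and non-overlapping; an empty list is
    a valid result.
    """
    above = velocity.v > noise.eta
    return [
        SaccadeEvent(onset_ms=int(velocity.t_ms[a]), offset_ms=int(velocity.t_ms[b - 1]))
        for a, b in _supra_runs(above, min_run)
    ]


def saccade_metrics(event: SaccadeEvent, stream: SampleStream, velocity: VelocitySignal,
                    screen: ScreenGeometry = ScreenGeometry()) -> SaccadeEvent:
    """Fill in amplitude, peak velocity and direction of a detected event.

    Amplitude is the Euclidean norm of the per-axis visual-angle
    displacement between gaze at onset and at offset; peak velocity the
    maximum combined speed within the event; direction the atan2 angle of
    the displacement with screen-up = +90°.
    """
    i0 = int(np.searchsorted(stream.t_ms, event.onset_ms))
    i1 = int(np.searchsorted(stream.t_ms, event.offset_ms))
    if not (0 <= i0 <= i1 < len(stream)):
        raise ValueError("event lies outside the stream")
    cx, cy = screen.center_px
    dx = px_to_deg(stream.x_px[i1] - cx, screen) - px_to_deg(stream.x_px[i0] - cx, screen)
    dy = px_to_deg(stream.y_px[i1] - cy, screen) - px_to_deg(stream.y_px[i0] - cy, screen)
    event.amplitude_deg = math.hypot(dx, dy)
    event.peak_velocity_dps = float(np.max(velocity.v[i0 : i1 + 1]))
    # screen y grows downward; negate for the conventional up-positive angle
    event.direction_deg = math.degrees(math.atan2(-dy, dx)) if event.amplitude_deg > 0 else float("nan")
    event.participant = stream.meta.get("participant")
    event.condition = stream.meta.get("condition")
    event.is_transition = event.onset_ms < stream.meta.get("transition_end_ms", 0)
    return event


def extract_fixations(stream: SampleStream, events: list[SaccadeEvent],
                      guard_ms: int = 20) -> list[FixationWindow]:
    """Fixation windows between detected saccades, trimmed by ``guard_ms``
    at both ends so transient samples around each event are excluded.

    Windows are attributed to planned targets through the stream's
    ground-truth fixation segments when available (simulated data), else
    numbered sequentially.  Targets whose window would be empty after
    trimming are omitted.
    """
    n = len(stream)
    in_event = np.zeros(n, dtype=bool)
    for ev in events:
        i0 = max(0, ev.onset_ms - guard_ms)
        i1 = min(n, ev.offset_ms + 1 + guard_ms)
        in_event[i0:i1] = True

    targets = stream.meta.get("targets_px")
    fix_segments = stream.meta.get("fix_segments")
    windows: list[FixationWindow] = []
    if fix_segments is not None:
        spans = [(a, b, idx) for a, b, idx in fix_segments]
    else:
        spans = [(a, b, k) for k, (a, b) in enumerate(_supra_runs(~in_event, 1))]

    for a, b, idx in spans:
        sel = np.zeros(n, dtype=bool)
        sel[a:b] = True
        sel &= ~in_event
        m = int(sel.sum())
        if m == 0:
            continue
        planned = tuple(targets[idx]) if targets is not None and 0 <= idx < len(targets) else (float("nan"),) * 2
        windows.append(
            FixationWindow(
                target_index=idx,
                planned_px=planned,
                start_ms=int(np.flatnonzero(sel)[0]),
                end_ms=int(np.flatnonzero(sel)[-1]) + 1,
                mean_x=float(stream.x_px[sel].mean()),
                mean_y=float(stream.y_px[sel].mean()),
                sd_x=float(stream.x_px[sel].std(ddof=1)) if m > 1 else 0.0,
                sd_y=float(stream.y_px[sel].std(ddof=1)) if m > 1 else 0.0,
                mean_pupil_au=float(stream.pupil_au[sel].mean()),
                n_samples=m,
            )
        )
    return windows
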