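"""Tracker-quality metrics and the main-sequence analysis.

Accuracy is the deviation of the mean measured fixation position from the
planned target; precision the dispersion of repeated measurements of the
same target.  Both are reported per calibration coordinate in pixels,
millimetres and degrees of visual angle.  The main sequence is the linear
amplitude / peak-velocity relationship of saccades; its fitted peak
velocity at a 10° amplitude (v10) is the per-participant, per-condition
summary entered into the brightness inference.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .detect import FixationWindow, SaccadeEvent
from .geometry import ScreenGeometry, px_to_deg, px_to_mm

__all__ = [
    "MainSequenceFit",
    "accuracy_table",
    "precision_table",
    "flag_fragments",
    "exclusion_filter",
    "events_to_frame",
    "main_sequence_fit",
    "per_condition_v10",
]


@dataclass(frozen=True)
class MainSequenceFit:
    """OLS fit of peak velocity (deg/s) on amplitude (deg)."""

    slope: float
    intercept: float
    r_squared: float
    n_saccades: int

    @property
    def v10(self) -> float:
        """Fitted peak velocity at a 10° amplitude."""
        return self.intercept + 10.0 * self.slope

    def predict(self, amplitude_deg):
        return self.intercept + self.slope * np.asarray(amplitude_deg, dtype=float)


def _group_windows(fixations_by_trial: list[list[FixationWindow]]) -> dict[int, list[FixationWindow]]:
    groups: dict[int, list[FixationWindow]] = {}
    for trial in fixations_by_trial:
        for w in trial:
            groups.setdefault(w.target_index, []).append(w)
    return groups


def accuracy_table(
    fixations_by_trial: list[list[FixationWindow]],
    screen: ScreenGeometry = ScreenGeometry(),
) -> pd.DataFrame:
    """Per-coordinate accuracy: mean measured fixation position over
    trials versus the planned coordinate, per axis in px / mm / deg.

    Rows are calibration coordinates; coordinates with no surviving
    window in any trial are flagged absent (NaN row) with a warning.
    """
    groups = _group_windows(fixations_by_trial)
    rows = []
    for idx in sorted(groups):
        ws = groups[idx]
        planned = ws[0].planned_px
        mx = float(np.mean([w.mean_x for w in ws]))
        my = float(np.mean([w.mean_y for w in ws]))
        dev_x, dev_y = mx - planned[0], my - planned[1]
        rows.append(
            {
                "target_index": idx,
                "planned_x_px": planned[0],
                "planned_y_px": planned[1],
                "mean_x_px": mx,
                "mean_y_px": my,
                "n_trials": len(ws),
                "dev_x_px": dev_x,
                "dev_y_px": dev_y,
                "dev_x_mm": px_to_mm(dev_x, screen),
                "dev_y_mm": px_to_mm(dev_y, screen),
                "dev_x_deg": px_to_deg(dev_x, screen),
                "dev_y_deg": px_to_deg(dev_y, screen),
            }
        )
    return pd.DataFrame(rows)


def precision_table(
    fixations_by_trial: list[list[FixationWindow]],
    screen: ScreenGeometry = ScreenGeometry(),
    method: str = "pooled_raw",
) -> pd.DataFrame:
    """Per-coordinate precision over repeated trials, per axis in
    px / mm / deg.

    ``pooled_raw`` (default) is the SD of all raw fixation samples of a
    coordinate around their grand mean, pooled over trials — computable
    from the per-window summary statistics as
    ``SS = sum[(n_i - 1) sd_i^2 + n_i (mean_i - grand)^2]``.
    ``trial_means`` is the SD of the per-trial window means instead.
    Requires at least two trials per coordinate.
    """
    if method not in ("pooled_raw", "trial_means"):
        raise ValueError(f"unknown method {method!r}")
    groups = _group_windows(fixations_by_trial)
    rows = []
    for idx in sorted(groups):
        ws = groups[idx]
        if len(ws) < 2:
            raise ValueError(f"coordinate {idx}: precision needs >= 2 trials, got {len(ws)}")
        out = {"target_index": idx, "planned_x_px": ws[0].planned_px[0],
               "planned_y_px": ws[0].planned_px[1], "n_trials": len(ws)}
        for axis, mean_attr, sd_attr in (("x", "mean_x", "sd_x"), ("y", "mean_y", "sd_y")):
            means = np.array([getattr(w, mean_attr) for w in ws])
            if method == "trial_means":
                sd = float(np.std(means, ddof=1))
            else:
                ns = np.array([w.n_samples for w in ws])
                sds = np.array([getattr(w, sd_attr) for w in ws])
                grand = float(np.sum(ns * means) / np.sum(ns))
                ss = float(np.sum((ns - 1) * sds**2 + ns * (means - grand) ** 2))
                sd = math.sqrt(ss / (np.sum(ns) - 1))
            out[f"sd_{axis}_px"] = sd
            out[f"sd_{axis}_mm"] = px_to_mm(sd, screen)
            out[f"sd_{axis}_deg"] = px_to_deg(sd, screen)
        rows.append(out)
    return pd.DataFrame(rows)


def flag_fragments(events: list[SaccadeEvent], stream_len: int, min_gap_ms: int = 20) -> list[SaccadeEvent]:
    """Mark events that are likely fragments of a split saccade: offset at
    the stream edge, or separated from a neighbouring event by less than
    ``min_gap_ms`` (a saccade chopped in two by momentary tracking loss)."""
    for i, ev in enumerate(events):
        frag = ev.offset_ms >= stream_len - 1 or ev.onset_ms == 0
        if i > 0 and ev.onset_ms - events[i - 1].offset_ms < min_gap_ms:
            frag = True
            events[i - 1].is_fragment = True
        ev.is_fragment = ev.is_fragment or frag
    return events


def exclusion_filter(
    events: list[SaccadeEvent],
    amp_range_deg: tuple[float, float] = (4.0, 14.6),
) -> tuple[list[SaccadeEvent], dict[str, int]]:
    """Apply the saccade exclusion rules and account for every drop.

    Drops, in order of precedence: (a) saccades recorded during the
    transition between consecutive participants, (b) fragment-flagged
    events, (c) amplitudes outside ``amp_range_deg`` — the planned
    4.5-14.1° range widened by the tracker's acknowledged 0.5° tolerance.
    Returns the retained events and a per-reason count log.
    """
    lo, hi = amp_range_deg
    log = {"input": len(events), "transition": 0, "fragment": 0, "amplitude": 0, "retained": 0}
    kept = []
    for ev in events:
        if ev.is_transition:
            log["transition"] += 1
        elif ev.is_fragment:
            log["fragment"] += 1
        elif not (lo <= ev.amplitude_deg <= hi):
            log["amplitude"] += 1
        else:
            kept.append(ev)
    log["retained"] = len(kept)
    return kept, log


def events_to_frame(events: list[SaccadeEvent]) -> pd.DataFrame:
    """Tabulate saccade events (one row per event)."""
    return pd.DataFrame(
        {
            "onset_ms": [e.onset_ms for e in events],
            "offset_ms": [e.offset_ms for e in events],
            "amplitude_deg": [e.amplitude_deg for e in events],
            "peak_velocity_dps": [e.peak_velocity_dps for e in events],
            "direction_deg": [e.direction_deg for e in events],
            "participant": [e.participant for e in events],
            "condition": [e.condition for e in events],
            "is_transition": [e.is_transition for e in events],
            "is_fragment": [e.is_fragment for e in events],
        }
    )


def main_sequence_fit(amplitude_deg, peak_velocity_dps) -> MainSequenceFit:
    """Ordinary least squares of peak velocity on amplitude (raw values;
    the amplitude filter keeps the fit inside the linear regime of the
    main sequence).  Needs >= 3 saccades at >= 2 distinct amplitudes."""
    a = np.asarray(amplitude_deg, dtype=float)
    v = np.asarray(peak_velocity_dps, dtype=float)
    if a.size < 3:
        raise ValueError("main-sequence fit needs at least 3 saccades")
    if np.ptp(a) == 0:
        raise ValueError("degenerate design: all amplitudes identical")
    slope, intercept = np.polyfit(a, v, 1)
    resid = v - (intercept + slope * a)
    ss_tot = float(np.sum((v - v.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return MainSequenceFit(slope=float(slope), intercept=float(intercept),
                           r_squared=r2, n_saccades=int(a.size))


def per_condition_v10(
    saccades: pd.DataFrame,
    min_saccades: int = 3,
) -> tuple[pd.DataFrame, dict[str, MainSequenceFit]]:
    """Fitted 10° peak velocity per participant and condition, plus grand
    per-condition fits pooling all participants.

    ``saccades`` must have columns participant, condition, amplitude_deg,
    peak_velocity_dps (retained saccades only).  Participants with fewer
    than ``min_saccades`` saccades in any condition are excluded with a
    warning, mirroring the empty-dataset exclusions of a real run.
    Returns (wide participants x conditions v10 matrix, grand fits).
    """
    conditions = list(dict.fromkeys(saccades["condition"]))
    rows = {}
    dropped = []
    for p, g in saccades.groupby("participant", sort=True):
        vals = {}
        for c in conditions:
            gc = g[g["condition"] == c]
            if len(gc) < min_saccades:
                vals = None
                break
            vals[c] = main_sequence_fit(gc["amplitude_deg"], gc["peak_velocity_dps"]).v10
        if vals is None:
            dropped.append(p)
        else:
            rows[p] = vals
    if dropped:
        warnings.warn(f"excluded {len(dropped)} participant(s) with < {min_saccades} "
                      f"saccades in some condition: {dropped}")
    matrix = pd.DataFrame.from_dict(rows, orient="index")[conditions]
    matrix.index.name = "participant"
    grand = {
        c: main_sequence_fit(
            saccades.loc[saccades["condition"] == c, "amplitude_deg"],
            saccades.loc[saccades["condition"] == c, "peak_velocity_dps"],
        )
        for c in conditions
    }
    return matrix, grand
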