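"""End-to-end orchestration: simulate, detect, measure, infer.

Two canonical runs mirror the two halves of a rig evaluation:

* :func:`run_accuracy_precision` — repeated trials of the calibration
  grid (and single-line patterns), yielding per-coordinate accuracy and
  precision tables in px / mm / deg.
* :func:`run_brightness_experiment` — the full null experiment: random
  saccade plans replayed identically under three brightness labels,
  saccade detection and exclusion filtering, per-condition main-sequence
  fits (v10), and the repeated-measures ANOVAs for peak velocity and
  pupil size against brightness.

Every run is fully determined by ``(RunConfig, seed)`` and can emit a
manifest with per-file checksums to prove it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .detect import (
    FixationWindow,
    SaccadeEvent,
    VelocitySignal,
    detect_saccades,
    estimate_noise_sigma,
    extract_fixations,
    sg_velocity,
)
from .metrics import (
    accuracy_table,
    events_to_frame,
    exclusion_filter,
    flag_fragments,
    main_sequence_fit,
    per_condition_v10,
    precision_table,
)
from .rig import (
    Pattern,
    SampleStream,
    TrialPlan,
    plan_calibration_grid,
    plan_line_pattern,
    simulate_experiment,
    simulate_trial,
)
from .stats import pupil_direction_analysis, rm_anova

log = logging.getLogger("gazerig")

__all__ = ["analyze_stream", "run_pattern_trials", "run_accuracy_precision",
           "run_brightness_experiment", "write_manifest"]


def analyze_stream(stream: SampleStream, screen, guard_ms: int = 20):
    """The full per-stream analysis chain: SG velocity, adaptive noise
    threshold, saccade detection, metrics, fragment flags, fixations.

    Returns ``(velocity, noise, events, fixations)``.
    """
    from .detect import saccade_metrics

    vel = sg_velocity(stream, screen=screen)
    noise = estimate_noise_sigma(vel)
    events = detect_saccades(vel, noise)
    for ev in events:
        saccade_metrics(ev, stream, vel, screen)
    flag_fragments(events, len(stream))
    fixations = extract_fixations(stream, events, guard_ms=guard_ms)
    return vel, noise, events, fixations


def run_pattern_trials(config: RunConfig, pattern: Pattern, n_trials: int | None = None
                       ) -> list[list[FixationWindow]]:
    """Simulate ``n_trials`` recordings of one pattern and extract the
    per-trial fixation windows.

    The motor positioning error is seeded once per pattern, not per
    trial: the drive train's repositioning is repeatable, so the error is
    a systematic per-coordinate bias that shows up in accuracy, while the
    trial-to-trial dispersion (precision) reflects tracker noise alone.
    """
    n_trials = n_trials if n_trials is not None else config.n_trials
    screen, camera, motor = config.screen.build(), config.camera.build(), config.motor.build()
    name_tag = int.from_bytes(pattern.name.encode()[:4].ljust(4, b"\0"), "big")
    ss = np.random.SeedSequence([config.seed, name_tag])
    m_ss, noise_root = ss.spawn(2)
    out = []
    for n_ss in noise_root.spawn(n_trials):
        plan = TrialPlan(participant_id=0, condition="grid", targets=pattern.targets,
                         fixation_ms=config.fixation_ms)
        stream = simulate_trial(
            plan, cfg=motor, screen=screen, camera=camera,
            noise_sd_deg=config.noise_sd_deg, pupil_base_au=config.pupil_base_au,
            pupil_noise_au=config.pupil_noise_au, motion_seed=m_ss, noise_seed=n_ss,
        )
        _, _, _, fixations = analyze_stream(stream, screen)
        out.append(fixations)
    return out


def run_accuracy_precision(config: RunConfig, out_dir=None) -> dict:
    """Accuracy and precision tables for the calibration grid and the
    single horizontal/vertical line patterns over repeated trials."""
    screen = config.screen.build()
    patterns = [plan_calibration_grid(screen),
                plan_line_pattern("h", screen=screen),
                plan_line_pattern("v", screen=screen)]
    results: dict = {"config": config}
    for pat in patterns:
        log.info("pattern %s: simulating %d trials", pat.name, config.n_trials)
        fixations = run_pattern_trials(config, pat)
        acc = accuracy_table(fixations, screen)
        prec = precision_table(fixations, screen)
        results[pat.name] = {"fixations": fixations, "accuracy": acc, "precision": prec}
        log.info("pattern %s: %d coordinates, max |dev| %.3f°", pat.name, len(acc),
                 acc[["dev_x_deg", "dev_y_deg"]].abs().to_numpy().max())
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for pat in patterns:
            results[pat.name]["accuracy"].to_csv(out_dir / f"accuracy_{pat.name}.csv", index=False)
            results[pat.name]["precision"].to_csv(out_dir / f"precision_{pat.name}.csv", index=False)
        write_manifest(config, out_dir)
    return results


def run_brightness_experiment(config: RunConfig, out_dir=None, shared_noise: bool = False) -> dict:
    """The full null experiment and its inference.

    Simulates ``n_participants`` random plans replayed under every
    brightness condition, runs detection and the exclusion filter, fits
    the per-participant and grand main sequences, and enters v10 and the
    fixation pupil means into repeated-measures ANOVAs with brightness as
    the within-subject factor.
    """
    screen, camera, motor = config.screen.build(), config.camera.build(), config.motor.build()
    rows = []
    pupil_rows = []
    agg_log = {"input": 0, "transition": 0, "fragment": 0, "amplitude": 0, "retained": 0}
    streams = simulate_experiment(
        n_participants=config.n_participants, n_saccades=config.n_saccades,
        conditions=config.conditions, seed=config.seed, shared_noise=shared_noise,
        cfg=motor, screen=screen, camera=camera, noise_sd_deg=config.noise_sd_deg,
        pupil_base_au=config.pupil_base_au, pupil_noise_au=config.pupil_noise_au,
    )
    for stream in streams:
        _, _, events, fixations = analyze_stream(stream, screen)
        kept, xlog = exclusion_filter(events)
        for k in agg_log:
            agg_log[k] += xlog[k]
        p, c = stream.meta["participant"], stream.meta["condition"]
        for ev in kept:
            rows.append((p, c, ev.amplitude_deg, ev.peak_velocity_dps))
        for w in fixations:
            pupil_rows.append((p, c, w.target_index, w.mean_pupil_au))
    saccades = pd.DataFrame(rows, columns=["participant", "condition", "amplitude_deg",
                                           "peak_velocity_dps"])
    log.info("exclusion log: %s", agg_log)

    v10_matrix, grand_fits = per_condition_v10(saccades)
    v10_anova = rm_anova(v10_matrix.to_numpy())

    pupil = pd.DataFrame(pupil_rows, columns=["participant", "condition", "fixation", "pupil_au"])
    pupil_wide = pupil.pivot_table(index=["participant", "fixation"], columns="condition",
                                   values="pupil_au")[list(config.conditions)].dropna()
    pupil_anova = rm_anova(pupil_wide.to_numpy())

    results = {
        "config": config,
        "saccades": saccades,
        "exclusion_log": agg_log,
        "v10_matrix": v10_matrix,
        "grand_fits": grand_fits,
        "v10_anova": v10_anova,
        "pupil_matrix": pupil_wide,
        "pupil_anova": pupil_anova,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        saccades.round(3).to_csv(out_dir / "saccades.csv", index=False)
        v10_matrix.round(3).to_csv(out_dir / "v10_matrix.csv")
        summary = {
            "exclusion_log": agg_log,
            "grand_v10": {c: f.v10 for c, f in grand_fits.items()},
            "v10_anova": v10_anova.summary(),
            "pupil_anova": pupil_anova.summary(),
        }
        (out_dir / "summary.json").write_text(json.dumps(summary, indent=1))
        write_manifest(config, out_dir)
    return results


def run_pupil_direction(config: RunConfig, out_dir=None):
    """Gaze-direction pupil bias on repeated calibration-grid trials."""
    screen = config.screen.build()
    fixations = run_pattern_trials(config, plan_calibration_grid(screen))
    res = pupil_direction_analysis(fixations, split_seed=config.seed)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "pupil_direction.json").write_text(json.dumps({
            "means_au": res.means_au,
            "percent_dev": res.percent_dev,
            "range_mm_horizontal": res.range_mm_horizontal,
            "range_mm_vertical": res.range_mm_vertical,
            "horizontal": res.horizontal.summary(),
            "vertical": res.vertical.summary(),
        }, indent=1))
        write_manifest(config, out_dir)
    return res


def write_manifest(config: RunConfig, out_dir) -> Path:
    """Checksum every file in ``out_dir`` and record the config hash, so
    a run can be verified to regenerate bit-identically."""
    out_dir = Path(out_dir)
    checksums = {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(out_dir.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = {"config_hash": config.hash(), "seed": config.seed, "checksums": checksums}
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1))
    return path
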