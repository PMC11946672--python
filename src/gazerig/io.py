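"""Text-based file formats for streams, events, fixations and reports.

Streams are TSV (t_ms, x_px, y_px, pupil_au; positions rounded to 3
decimal pixels) with a JSON sidecar carrying the metadata; an optional
export writes an ASC-like dialect (``SAMPLE <t> <x> <y> <pupil>`` lines)
for interoperability with common gaze tooling.  Events and fixation
tables are CSV.  All round-trips are lossless to the stated precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .detect import FixationWindow, SaccadeEvent
from .metrics import events_to_frame
from .rig import SampleStream

__all__ = [
    "write_stream_tsv",
    "read_stream_tsv",
    "write_stream_asc",
    "write_events_csv",
    "read_events_csv",
    "write_fixations_csv",
]

_STREAM_COLS = ["t_ms", "x_px", "y_px", "pupil_au"]


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_stream_tsv(stream: SampleStream, path) -> None:
    """Write a stream as TSV plus a ``<path>.meta.json`` sidecar."""
    path = Path(path)
    df = stream.to_frame()
    for c in ("x_px", "y_px", "pupil_au"):
        df[c] = df[c].round(3)
    df.to_csv(path, sep="\t", index=False)
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    sidecar.write_text(json.dumps({"fs_hz": stream.fs_hz, "meta": _jsonable(stream.meta)}, indent=1))


def read_stream_tsv(path) -> SampleStream:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as e:  # pragma: no cover - pandas reports the line
        raise ValueError(f"malformed stream file {path}: {e}") from e
    missing = set(_STREAM_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing stream columns {sorted(missing)} (header line 1)")
    meta, fs = {}, 1000
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    if sidecar.exists():
        blob = json.loads(sidecar.read_text())
        fs = blob.get("fs_hz", 1000)
        meta = blob.get("meta", {})
        for key in ("targets_px",):
            if key in meta:
                meta[key] = np.asarray(meta[key], dtype=float)
        for key in ("fix_segments", "move_segments"):
            if key in meta:
                meta[key] = [tuple(t) for t in meta[key]]
    return SampleStream(
        t_ms=df["t_ms"].to_numpy(np.int64),
        x_px=df["x_px"].to_numpy(float),
        y_px=df["y_px"].to_numpy(float),
        pupil_au=df["pupil_au"].to_numpy(float),
        fs_hz=fs,
        meta=meta,
    )


def write_stream_asc(stream: SampleStream, path) -> None:
    """ASC-like text export: one ``SAMPLE`` line per sample."""
    with open(path, "w") as fh:
        fh.write(f"** RATE {stream.fs_hz:.2f}\n")
        for t, x, y, p in zip(stream.t_ms, stream.x_px, stream.y_px, stream.pupil_au):
            fh.write(f"SAMPLE\t{t}\t{x:.3f}\t{y:.3f}\t{p:.3f}\n")


def write_events_csv(events: list[SaccadeEvent], path) -> None:
    df = events_to_frame(events)
    for c in ("amplitude_deg", "peak_velocity_dps", "direction_deg"):
        df[c] = df[c].round(3)
    df.to_csv(path, index=False)


def read_events_csv(path) -> list[SaccadeEvent]:
    df = pd.read_csv(path)
    events = []
    for _, r in df.iterrows():
        events.append(
            SaccadeEvent(
                onset_ms=int(r["onset_ms"]),
                offset_ms=int(r["offset_ms"]),
                amplitude_deg=float(r["amplitude_deg"]),
                peak_velocity_dps=float(r["peak_velocity_dps"]),
                direction_deg=float(r["direction_deg"]),
                participant=None if pd.isna(r.get("participant")) else int(r["participant"]),
                condition=None if pd.isna(r.get("condition")) else str(r["condition"]),
                is_transition=bool(r.get("is_transition", False)),
                is_fragment=bool(r.get("is_fragment", False)),
            )
        )
    return events


def write_fixations_csv(fixations: list[FixationWindow], path) -> None:
    pd.DataFrame(
        {
            "target_index": [w.target_index for w in fixations],
            "planned_x_px": [w.planned_px[0] for w in fixations],
            "planned_y_px": [w.planned_px[1] for w in fixations],
            "start_ms": [w.start_ms for w in fixations],
            "end_ms": [w.end_ms for w in fixations],
            "mean_x_px": [round(w.mean_x, 3) for w in fixations],
            "mean_y_px": [round(w.mean_y, 3) for w in fixations],
            "sd_x_px": [round(w.sd_x, 4) for w in fixations],
            "sd_y_px": [round(w.sd_y, 4) for w in fixations],
            "mean_pupil_au": [round(w.mean_pupil_au, 3) for w in fixations],
            "n_samples": [w.n_samples for w in fixations],
        }
    ).to_csv(path, index=False)
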