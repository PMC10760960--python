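"""Readers and writers for the plain-text and TIFF interchange formats.

Track tables are CSV with columns ``track_id, frame, t_s, x_um, y_um``;
angle traces ``t_s, theta_deg, epoch``; envelopes
``arc_um, amp_above_um, amp_below_um``; decay series
``condition, t_min, motile_pct[, n_cells]``; CAI tables
``subject_id, motile_A_pct, motile_B_pct, readout_min``; calcium traces
``t_s, F[, cell_id]`` with events in a JSON list of ``{label, t_s}``.
Image stacks are multi-page uint16 TIFF.  Generator outputs carry a JSON
metadata sidecar recording the spec and seed.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .catsper import MotilityTimeSeries
from .flagbeat import AngleTrace, BeatEnvelope
from .signals import CalciumTrace
from .trackkin import ImageStack, Track

__all__ = [
    "write_tracks_csv",
    "read_tracks_csv",
    "write_stack_tiff",
    "read_stack_tiff",
    "write_angle_trace_csv",
    "read_angle_trace_csv",
    "write_envelope_csv",
    "read_envelope_csv",
    "write_decay_csv",
    "read_decay_csv",
    "read_cai_table_csv",
    "write_calcium_csv",
    "read_calcium_csv",
    "write_metadata",
    "read_metadata",
]


def write_metadata(path: str | Path, payload: dict) -> None:
    """Write a JSON metadata sidecar (specs are serialized field-by-field)."""

    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(payload, indent=2, default=default))


def read_metadata(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def write_tracks_csv(path: str | Path, tracks: list[Track]) -> None:
    rows = []
    for tr in tracks:
        frames = np.round((tr.t - tr.t[0]) * tr.frame_rate).astype(int)
        base_frame = int(round(tr.t[0] * tr.frame_rate))
        for f, t, x, y in zip(frames + base_frame, tr.t, tr.x, tr.y):
            rows.append((tr.track_id, int(f), t, x, y))
    pd.DataFrame(rows, columns=["track_id", "frame", "t_s", "x_um", "y_um"]).to_csv(
        path, index=False
    )


def read_tracks_csv(
    path: str | Path, frame_rate: float | None = None, pixel_size: float = 1.0
) -> list[Track]:
    df = pd.read_csv(path)
    tracks = []
    for tid, grp in df.groupby("track_id", sort=False):
        t = grp["t_s"].to_numpy(dtype=float)
        fr = frame_rate if frame_rate is not None else 1.0 / float(np.median(np.diff(t)))
        tracks.append(
            Track(
                track_id=str(tid), t=t,
                x=grp["x_um"].to_numpy(dtype=float),
                y=grp["y_um"].to_numpy(dtype=float),
                frame_rate=fr, pixel_size=pixel_size,
            )
        )
    return tracks


def write_stack_tiff(path: str | Path, stack: ImageStack) -> None:
    data = np.clip(np.round(stack.frames), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(path, data, metadata={
        "frame_rate": stack.frame_rate, "pixel_size_um": stack.pixel_size,
    })


def read_stack_tiff(path: str | Path, frame_rate: float, pixel_size: float) -> ImageStack:
    frames = tifffile.imread(path).astype(float)
    if frames.ndim == 2:
        frames = frames[None]
    return ImageStack(frames=frames, frame_rate=frame_rate, pixel_size=pixel_size)


def write_angle_trace_csv(path: str | Path, trace: AngleTrace) -> None:
    pd.DataFrame(
        {"t_s": trace.times, "theta_deg": trace.theta, "epoch": trace.epoch}
    ).to_csv(path, index=False)


def read_angle_trace_csv(path: str | Path, frame_rate: float | None = None) -> AngleTrace:
    df = pd.read_csv(path)
    t = df["t_s"].to_numpy(dtype=float)
    fr = frame_rate if frame_rate is not None else 1.0 / float(np.median(np.diff(t)))
    epoch = str(df["epoch"].iloc[0]) if "epoch" in df else "pre"
    return AngleTrace(
        times=t, theta=df["theta_deg"].to_numpy(dtype=float), frame_rate=fr, epoch=epoch
    )


def write_envelope_csv(path: str | Path, env: BeatEnvelope) -> None:
    pd.DataFrame(
        {
            "arc_um": env.arc_positions,
            "amp_above_um": env.amp_above,
            "amp_below_um": env.amp_below,
        }
    ).to_csv(path, index=False)


def read_envelope_csv(path: str | Path) -> BeatEnvelope:
    df = pd.read_csv(path)
    return BeatEnvelope(
        arc_positions=df["arc_um"].to_numpy(dtype=float),
        amp_above=df["amp_above_um"].to_numpy(dtype=float),
        amp_below=df["amp_below_um"].to_numpy(dtype=float),
    )


def write_decay_csv(path: str | Path, series: MotilityTimeSeries) -> None:
    df = pd.DataFrame(
        {
            "condition": series.condition,
            "t_min": series.times,
            "motile_pct": series.motile_fraction,
        }
    )
    if series.n_cells is not None:
        df["n_cells"] = series.n_cells
    df.to_csv(path, index=False)


def read_decay_csv(path: str | Path) -> list[MotilityTimeSeries]:
    df = pd.read_csv(path)
    out = []
    for cond, grp in df.groupby("condition", sort=False):
        n_cells = int(grp["n_cells"].iloc[0]) if "n_cells" in grp else None
        out.append(
            MotilityTimeSeries(
                condition=str(cond),
                times=grp["t_min"].to_numpy(dtype=float),
                motile_fraction=grp["motile_pct"].to_numpy(dtype=float),
                n_cells=n_cells,
            )
        )
    return out


def read_cai_table_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"subject_id", "motile_A_pct", "motile_B_pct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"CAI table missing columns: {sorted(missing)}")
    if "readout_min" not in df:
        df["readout_min"] = 15
    return df


def write_calcium_csv(path: str | Path, trace: CalciumTrace, events_path: str | Path) -> None:
    pd.DataFrame({"t_s": trace.times, "F": trace.F}).to_csv(path, index=False)
    Path(events_path).write_text(
        json.dumps([{"label": lab, "t_s": t} for lab, t in trace.events], indent=2)
    )


def read_calcium_csv(
    path: str | Path, events_path: str | Path, source: str = "population"
) -> CalciumTrace:
    df = pd.read_csv(path)
    events = tuple(
        (e["label"], float(e["t_s"])) for e in json.loads(Path(events_path).read_text())
    )
    return CalciumTrace(
        times=df["t_s"].to_numpy(dtype=float),
        F=df["F"].to_numpy(dtype=float),
        events=events, source=source,
    )
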