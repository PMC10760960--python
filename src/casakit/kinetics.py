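"""Time-resolved (kinetic) hyperactivation analysis.

Rapid mixing of sperm with a stimulus is followed by continuous dark-field
recording; short 1-second sub-sequences are extracted from fixed analysis
windows spread over the recording, analyzed by CASA, and pooled per window
to give a hyperactivation timecourse.  Subtracting the timecourse of a
buffer-only mixing control isolates the stimulus-evoked change.

The default window scheme covers 0-75 s in five 15-s windows plus two late
windows at 105-120 s and 165-180 s.  Windows are half-open ``[start, end)``
and contiguous over the first 75 s; a ``literal_gap_scheme`` reproducing
printed window bounds with 1-s gaps (0-15, 16-30, ...) is also provided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .trackkin import (
    DEFAULT_GATE,
    HyperactivationGate,
    Track,
    classify_hyperactive,
    kinematics,
)

__all__ = [
    "WindowScheme",
    "WindowGroup",
    "Timecourse",
    "default_scheme",
    "literal_gap_scheme",
    "window_tracks",
    "hyper_timecourse",
    "baseline_correct",
]


@dataclass(frozen=True)
class WindowScheme:
    """Ordered, non-overlapping analysis windows ``[start, end)`` in seconds."""

    windows: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "windows", tuple(tuple(w) for w in self.windows))
        if not self.windows:
            raise ValueError("need at least one window")
        prev_end = -math.inf
        for start, end in self.windows:
            if end <= start:
                raise ValueError("window end must exceed start")
            if start < prev_end:
                raise ValueError("windows must be non-overlapping and increasing")
            prev_end = end

    @property
    def mids(self) -> np.ndarray:
        return np.array([(a + b) / 2 for a, b in self.windows])


def default_scheme() -> WindowScheme:
    """Contiguous half-open windows: 5 x 15 s, then 105-120 s and 165-180 s."""
    return WindowScheme(
        (
            (0, 15), (15, 30), (30, 45), (45, 60), (60, 75),
            (105, 120), (165, 180),
        )
    )


def literal_gap_scheme() -> WindowScheme:
    """Window bounds as printed in assay protocols (with 1-s gaps)."""
    return WindowScheme(
        (
            (0, 15), (16, 30), (31, 45), (46, 60), (61, 75),
            (105, 120), (165, 180),
        )
    )


@dataclass(frozen=True)
class WindowGroup:
    """Tracks pooled from the 1-s sub-intervals of one analysis window."""

    window: tuple[float, float]
    tracks: tuple[Track, ...]
    subwindow_starts: tuple[float, ...]


@dataclass(frozen=True)
class Timecourse:
    """Per-window hyperactive fraction (%); missing windows are NaN."""

    window_mids: np.ndarray  # s
    hyper_frac: np.ndarray  # %
    condition: str
    scheme: WindowScheme


def _clip_track(track: Track, start: float, end: float) -> Track | None:
    mask = (track.t >= start) & (track.t < end)
    if np.count_nonzero(mask) < 2:
        return None
    return Track(
        track_id=track.track_id,
        t=track.t[mask],
        x=track.x[mask],
        y=track.y[mask],
        frame_rate=track.frame_rate,
        pixel_size=track.pixel_size,
    )


def window_tracks(
    tracks: list[Track],
    scheme: WindowScheme | None = None,
    n_subwindows: int = 3,
    subwindow_len: float = 1.0,
) -> list[WindowGroup]:
    """Assign tracks to the 1-s sub-intervals of each analysis window.

    Per window, ``n_subwindows`` sub-intervals of ``subwindow_len`` seconds
    are placed evenly from the window start to ``end - subwindow_len``
    (e.g. 0, 7, 14 s for a [0, 15) window with 3 sub-intervals).  Each track
    is clipped to the first sub-interval it overlaps with at least two
    samples and contributes once per window; sub-interval groups are pooled.
    """
    if scheme is None:
        scheme = default_scheme()
    if n_subwindows < 1:
        raise ValueError("n_subwindows must be >= 1")
    if not tracks:
        raise ValueError("no tracks")
    t_max = max(float(tr.t[-1]) for tr in tracks)
    if scheme.windows[-1][0] >= t_max:
        raise ValueError(
            f"window scheme extends to {scheme.windows[-1][1]} s but the "
            f"recording ends at {t_max:.2f} s"
        )
    groups: list[WindowGroup] = []
    for start, end in scheme.windows:
        if n_subwindows == 1:
            starts = np.array([start])
        else:
            starts = np.linspace(start, end - subwindow_len, n_subwindows)
        pooled: list[Track] = []
        for tr in tracks:
            for s0 in starts:
                clipped = _clip_track(tr, s0, s0 + subwindow_len)
                if clipped is not None:
                    pooled.append(clipped)
                    break  # single assignment per window
        groups.append(
            WindowGroup(
                window=(start, end), tracks=tuple(pooled),
                subwindow_starts=tuple(float(s) for s in starts),
            )
        )
    return groups


def hyper_timecourse(
    groups: list[WindowGroup],
    condition: str = "treated",
    vap_window: int = 5,
    gate: HyperactivationGate = DEFAULT_GATE,
) -> Timecourse:
    """Percent of pooled tracks per window that pass the hyperactivation gate.

    An empty window is reported as NaN (missing), not as 0 %.
    """
    if not groups:
        raise ValueError("no window groups")
    mids = []
    fracs = []
    for g in groups:
        mids.append((g.window[0] + g.window[1]) / 2)
        if not g.tracks:
            fracs.append(math.nan)
            continue
        n_hyper = sum(
            classify_hyperactive(kinematics(tr, vap_window=vap_window, gate=gate), gate)
            for tr in g.tracks
        )
        fracs.append(100.0 * n_hyper / len(g.tracks))
    scheme = WindowScheme(tuple(g.window for g in groups))
    return Timecourse(
        window_mids=np.array(mids), hyper_frac=np.array(fracs),
        condition=condition, scheme=scheme,
    )


def baseline_correct(
    treated: Timecourse, control: Timecourse, anchor_first: bool = False
) -> Timecourse:
    """Stimulus-evoked change: treated minus buffer-only control, per window.

    With a steady control the resulting delta is already zero before the
    stimulus acts, which matches plotting the change relative to the
    control level at t = 0.  ``anchor_first=True`` additionally shifts the
    delta so the first window is exactly 0; note this also nulls any real
    response confined to the first window, so it is appropriate only when
    the first window precedes the response.
    """
    if treated.scheme.windows != control.scheme.windows:
        raise ValueError("treated and control use different window schemes")
    delta = treated.hyper_frac - control.hyper_frac
    if anchor_first:
        delta = delta - delta[0]
    return Timecourse(
        window_mids=treated.window_mids.copy(), hyper_frac=delta,
        condition=f"{treated.condition} - {control.condition}", scheme=treated.scheme,
    )
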