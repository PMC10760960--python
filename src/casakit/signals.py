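"""Fluorescence Ca2+-trace processing.

Raw fluorescence F(t) is converted to a percent change over the mean basal
fluorescence, dF/F0 (%), and response amplitudes are normalized to the
maximal signal evoked by the Ca2+ ionophore ionomycin applied at the end of
each recording.  The stimulus-evoked waveform is classified as biphasic
(fast transient + sustained component), monophasic (single slow rise), or
absent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "CalciumTrace",
    "NormalizedResponse",
    "dff0",
    "response_amplitudes",
    "single_cell_normalize",
]

IONOMYCIN_LABEL = "ionomycin"


@dataclass(frozen=True)
class CalciumTrace:
    """Fluorescence time series with stimulus and ionomycin event markers."""

    times: np.ndarray  # s
    F: np.ndarray  # a.u.
    events: tuple  # of (label, time_s); must include an "ionomycin" event
    source: str = "population"  # or "single_cell"

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        f = np.asarray(self.F, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "F", f)
        object.__setattr__(self, "events", tuple(self.events))
        if t.size != f.size or t.size < 4:
            raise ValueError("times and F must be equal-length with >= 4 samples")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.source not in ("population", "single_cell"):
            raise ValueError("source must be 'population' or 'single_cell'")
        for label, et in self.events:
            if not t[0] <= et <= t[-1]:
                raise ValueError(f"event {label!r} at {et} s lies outside the trace")
        stim = self.stimulus_time
        iono = self.ionomycin_time
        if stim is not None and iono is not None and iono <= stim:
            raise ValueError("ionomycin event must follow the stimulus event")

    @property
    def stimulus_time(self) -> float | None:
        for label, et in self.events:
            if label != IONOMYCIN_LABEL:
                return float(et)
        return None

    @property
    def ionomycin_time(self) -> float | None:
        for label, et in self.events:
            if label == IONOMYCIN_LABEL:
                return float(et)
        return None


@dataclass(frozen=True)
class NormalizedResponse:
    """Stimulus response amplitude relative to the ionomycin maximum."""

    dff0_max: float  # % (max between stimulus and ionomycin)
    iono_max: float  # % (max after ionomycin)
    rel_amp: float  # dimensionless, stimulus/ionomycin
    waveform_class: str  # "biphasic" | "monophasic" | "none"

    def __post_init__(self) -> None:
        if self.iono_max <= 0:
            raise ValueError("ionomycin amplitude must be positive")
        if self.rel_amp < 0:
            raise ValueError("rel_amp must be non-negative")
        if self.waveform_class not in ("biphasic", "monophasic", "none"):
            raise ValueError("invalid waveform_class")


def dff0(trace: CalciumTrace, guard_s: float = 1.0) -> np.ndarray:
    """Percent fluorescence change over the mean basal fluorescence.

    The baseline window is everything before the first event minus a
    ``guard_s`` guard band.  Invariant under multiplicative gain of F.
    """
    first_event = min(et for _, et in trace.events)
    mask = trace.times < first_event - guard_s
    if np.count_nonzero(mask) < 3:
        mask = trace.times < first_event
    if np.count_nonzero(mask) < 3:
        raise ValueError("baseline window must contain at least 3 samples")
    f0 = float(trace.F[mask].mean())
    if f0 <= 0:
        raise ValueError("mean basal fluorescence must be positive")
    return 100.0 * (trace.F - f0) / f0


def _classify_waveform(
    times: np.ndarray,
    seg: np.ndarray,
    iono_max: float,
    smooth_s: float,
    noise_floor_frac: float,
    trough_frac: float,
) -> str:
    if seg.size < 3:
        return "none"
    dt = float(np.median(np.diff(times)))
    w = max(int(round(smooth_s / dt)), 1)
    kernel = np.ones(w) / w
    smoothed = np.convolve(seg, kernel, mode="same")
    floor = noise_floor_frac * iono_max
    peaks, props = find_peaks(smoothed, height=floor)
    # a plateau that is still elevated at the segment end counts as a peak
    if smoothed[-1] >= floor and (peaks.size == 0 or peaks[-1] < seg.size - w):
        if smoothed[-1] >= smoothed[max(seg.size - 2 * w, 0)] - 1e-12:
            peaks = np.append(peaks, seg.size - 1)
    if peaks.size == 0:
        return "none"
    if peaks.size == 1:
        return "monophasic"
    heights = smoothed[peaks]
    top2 = peaks[np.argsort(heights)[-2:]]
    lo, hi = int(top2.min()), int(top2.max())
    trough = float(smoothed[lo : hi + 1].min())
    lower_peak = float(min(smoothed[lo], smoothed[hi]))
    if lower_peak - trough >= trough_frac * lower_peak:
        return "biphasic"
    return "monophasic"


def response_amplitudes(
    trace: CalciumTrace,
    guard_s: float = 1.0,
    smooth_s: float = 0.5,
    noise_floor_frac: float = 0.05,
    trough_frac: float = 0.10,
) -> NormalizedResponse:
    """Extract the stimulus response and normalize it to the ionomycin maximum.

    ``dff0_max`` is the peak dF/F0 between the stimulus and ionomycin
    events; ``iono_max`` the peak after ionomycin; ``rel_amp`` their ratio
    (clamped at 0 for traces that only dip).  The waveform class is decided
    on a ``smooth_s``-smoothed copy of the stimulus segment: two maxima
    above ``noise_floor_frac * iono_max`` separated by a trough at least
    ``trough_frac`` of the lower peak give "biphasic"; one gives
    "monophasic"; none gives "none".
    """
    if trace.ionomycin_time is None:
        raise ValueError("trace has no ionomycin event")
    d = dff0(trace, guard_s=guard_s)
    stim = trace.stimulus_time
    iono = trace.ionomycin_time
    start = stim if stim is not None else trace.times[0]
    seg_mask = (trace.times >= start) & (trace.times < iono)
    iono_mask = trace.times >= iono
    if not np.any(iono_mask):
        raise ValueError("no samples after the ionomycin event")
    iono_max = float(d[iono_mask].max())
    if iono_max <= 0:
        raise ValueError("invalid recording: no ionomycin response")
    seg = d[seg_mask]
    dff0_max = float(seg.max()) if seg.size else 0.0
    rel_amp = max(dff0_max, 0.0) / iono_max
    waveform = _classify_waveform(
        trace.times[seg_mask], seg, iono_max, smooth_s, noise_floor_frac, trough_frac
    )
    if rel_amp == 0.0:
        waveform = "none"
    return NormalizedResponse(
        dff0_max=dff0_max, iono_max=iono_max, rel_amp=rel_amp, waveform_class=waveform
    )


def single_cell_normalize(
    traces: list[CalciumTrace], **kwargs
) -> tuple[list[NormalizedResponse], dict]:
    """Apply :func:`response_amplitudes` per cell and summarize across cells.

    Returns the per-cell responses and a summary dict with the mean and SD
    of the ionomycin-normalized amplitude.
    """
    if not traces:
        raise ValueError("need at least one cell")
    responses = [response_amplitudes(tr, **kwargs) for tr in traces]
    rel = np.array([r.rel_amp for r in responses])
    summary = {
        "n_cells": len(responses),
        "rel_amp_mean": float(rel.mean()),
        "rel_amp_sd": float(rel.std(ddof=1)) if rel.size > 1 else 0.0,
    }
    return responses, summary
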