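"""Flagellar-beat analysis of head-tethered sperm.

A sperm tethered by its head rotates about the attachment point while the
flagellum beats, so the head-midpiece angle theta(t) is a linear ramp (the
rotation velocity Omega, deg/s) carrying a sinusoidal oscillation (the beat,
with frequency f and angular amplitude A).  :func:`fit_oscillation`
decomposes a trace in two stages: ordinary-least-squares slope for Omega,
then a nonlinear sine fit to the detrended residual seeded at the
periodogram peak.

The beat envelope records, per arc-length position along the flagellum, the
maximal displacement above and below the head-midpiece axis across a beat
cycle.  The asymmetry index contrasts the areas under the two envelope
halves,

    AI = |AUC_above - AUC_below| / (AUC_above + AUC_below),

so 0 means a perfectly symmetric beat and 1 a completely one-sided beat.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import periodogram

__all__ = [
    "AngleTrace",
    "OscillationFit",
    "PrePostDelta",
    "BeatEnvelope",
    "unwrap_angle",
    "fit_oscillation",
    "pre_post_compare",
    "beat_envelope",
    "asymmetry_index",
    "max_amplitude",
]


@dataclass(frozen=True)
class AngleTrace:
    """Unwrapped head-midpiece angle theta(t) in degrees, relative to t=0.

    ``epoch`` distinguishes the recording window before ("pre") and after
    ("post") photo-release of a stimulus.
    """

    times: np.ndarray  # s
    theta: np.ndarray  # deg, unwrapped
    frame_rate: float  # frames/s
    epoch: str = "pre"

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        th = np.asarray(self.theta, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "theta", th)
        if t.size != th.size or t.size < 2:
            raise ValueError("times and theta must be equal-length with >= 2 samples")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(np.abs(np.diff(th)) > 180.0):
            raise ValueError("theta must be unwrapped (no step may exceed 180 deg)")
        if self.epoch not in ("pre", "post"):
            raise ValueError("epoch must be 'pre' or 'post'")


@dataclass(frozen=True)
class OscillationFit:
    """Ramp + sine decomposition of an angle trace."""

    omega: float  # deg/s, rotation velocity (OLS slope)
    freq: float  # Hz
    amp: float  # deg
    phase: float  # rad in (-pi, pi]
    rss: float  # deg^2
    converged: bool

    def __post_init__(self) -> None:
        if self.freq < 0 or self.amp < 0:
            raise ValueError("freq and amp must be non-negative")


@dataclass(frozen=True)
class PrePostDelta:
    """Post-minus-pre change of the beat parameters (decrease is negative)."""

    dfreq: float  # Hz
    damp: float  # deg
    domega: float  # deg/s


@dataclass(frozen=True)
class BeatEnvelope:
    """Maximal flagellar displacement above/below the head-midpiece axis."""

    arc_positions: np.ndarray  # um along the flagellum
    amp_above: np.ndarray  # um
    amp_below: np.ndarray  # um

    def __post_init__(self) -> None:
        s = np.asarray(self.arc_positions, dtype=float)
        a = np.asarray(self.amp_above, dtype=float)
        b = np.asarray(self.amp_below, dtype=float)
        object.__setattr__(self, "arc_positions", s)
        object.__setattr__(self, "amp_above", a)
        object.__setattr__(self, "amp_below", b)
        if not (s.size == a.size == b.size) or s.size < 2:
            raise ValueError("envelope arrays must be equal-length with >= 2 points")
        if np.any(np.diff(s) <= 0):
            raise ValueError("arc_positions must be strictly increasing")
        if np.any(a < 0) or np.any(b < 0):
            raise ValueError("envelope amplitudes must be non-negative")


def unwrap_angle(
    raw_theta: np.ndarray,
    frame_rate: float,
    times: np.ndarray | None = None,
    epoch: str = "pre",
) -> AngleTrace:
    """Remove 360-degree jumps from a raw angle series and zero its start."""
    raw = np.asarray(raw_theta, dtype=float)
    if raw.size < 2:
        raise ValueError("need at least 2 samples")
    unwrapped = np.unwrap(raw, period=360.0)
    unwrapped = unwrapped - unwrapped[0]
    if times is None:
        times = np.arange(raw.size) / frame_rate
    return AngleTrace(times=times, theta=unwrapped, frame_rate=frame_rate, epoch=epoch)


def _sine(t: np.ndarray, amp: float, freq: float, phase: float) -> np.ndarray:
    return amp * np.sin(2 * np.pi * freq * t + phase)


def fit_oscillation(trace: AngleTrace, joint_refine: bool = False) -> OscillationFit:
    """Two-stage decomposition of theta(t) into rotation and oscillation.

    Stage 1: Omega = OLS slope of theta versus t.  Stage 2: nonlinear fit of
    ``A * sin(2*pi*f*t + phi)`` to the detrended residual, with f seeded at
    the residual periodogram peak and (A, phi) at the complex demodulate at
    that frequency.  ``joint_refine=True`` adds a final joint 4-parameter
    refinement (slope + sine).

    Degenerate traces (residual numerically zero) report amp = 0 with
    ``converged = False``; a periodogram peak at the Nyquist frequency
    raises an aliasing warning and also reports ``converged = False``.
    """
    t = trace.times - trace.times[0]
    th = trace.theta
    design = np.column_stack([t, np.ones_like(t)])
    (omega, intercept), *_ = np.linalg.lstsq(design, th, rcond=None)
    resid = th - (omega * t + intercept)
    scale = max(float(np.max(np.abs(th))), 1.0)
    if float(np.std(resid)) < 1e-10 * scale:
        return OscillationFit(
            omega=float(omega), freq=0.0, amp=0.0, phase=0.0,
            rss=float(np.sum(resid**2)), converged=False,
        )
    freqs, power = periodogram(resid, fs=trace.frame_rate)
    power[0] = 0.0
    peak = int(np.argmax(power))
    f0 = float(freqs[peak])
    aliased = peak == len(freqs) - 1
    if aliased:
        warnings.warn(
            "periodogram peak at the Nyquist frequency; oscillation likely aliased",
            stacklevel=2,
        )
    # complex demodulation at the periodogram peak for amplitude/phase seeds
    z = 2.0 * np.mean(resid * np.exp(-2j * np.pi * f0 * t))
    a0 = float(np.abs(z))
    phi0 = float(np.angle(z) + np.pi / 2)
    nyq = trace.frame_rate / 2
    amp, freq, phase, converged = a0, max(f0, 1e-6), phi0, False
    try:
        # alternate sine fit and slope re-estimation: the OLS slope of the
        # raw trace is slightly biased by the oscillation unless the window
        # holds an integer number of periods, so back-substitute twice
        for _ in range(2):
            popt, _ = curve_fit(
                _sine, t, resid, p0=[amp, freq, phase], maxfev=10000
            )
            amp, freq, phase = (float(v) for v in popt)
            (omega, intercept), *_ = np.linalg.lstsq(
                design, th - _sine(t, amp, freq, phase), rcond=None
            )
            resid = th - (omega * t + intercept)
        converged = True
    except RuntimeError:
        pass
    if amp < 0:
        amp, phase = -amp, phase + np.pi
    freq = abs(freq)
    if freq > nyq:
        aliased = True
    phase = float((phase + np.pi) % (2 * np.pi) - np.pi)
    if joint_refine and converged:
        def full(tt, om, b, a, f, ph):
            return om * tt + b + a * np.sin(2 * np.pi * f * tt + ph)

        try:
            popt, _ = curve_fit(
                full, t, th, p0=[omega, intercept, amp, freq, phase], maxfev=10000
            )
            omega, intercept, amp, freq, phase = (float(v) for v in popt)
            if amp < 0:
                amp, phase = -amp, phase + np.pi
            freq = abs(freq)
            phase = float((phase + np.pi) % (2 * np.pi) - np.pi)
        except RuntimeError:
            pass
    rss = float(np.sum((th - (omega * t + intercept + _sine(t, amp, freq, phase))) ** 2))
    return OscillationFit(
        omega=float(omega), freq=freq, amp=amp, phase=phase,
        rss=rss, converged=converged and not aliased,
    )


def pre_post_compare(fit_pre: OscillationFit, fit_post: OscillationFit) -> PrePostDelta:
    """Post-minus-pre parameter changes; a decrease is negative."""
    if not (fit_pre.converged and fit_post.converged):
        raise ValueError("both fits must be converged")
    return PrePostDelta(
        dfreq=fit_post.freq - fit_pre.freq,
        damp=fit_post.amp - fit_pre.amp,
        domega=fit_post.omega - fit_pre.omega,
    )


def beat_envelope(
    arc_positions: np.ndarray,
    centerlines: np.ndarray,
    head_axis: tuple[tuple[float, float], tuple[float, float]],
) -> BeatEnvelope:
    """Beat envelope from flagellar centerlines sharing an arc-length grid.

    ``centerlines`` has shape ``(n_frames, n_arc, 2)`` with (x, y) in um.
    ``head_axis`` is a pair of points (head, midpiece) defining the
    reference axis; "above" is the positive cross-product side of the axis
    direction.  Per arc position the envelope is the maximum signed
    perpendicular distance above and below the axis across the frames.
    """
    cl = np.asarray(centerlines, dtype=float)
    s = np.asarray(arc_positions, dtype=float)
    if cl.ndim != 3 or cl.shape[2] != 2:
        raise ValueError("centerlines must have shape (n_frames, n_arc, 2)")
    if cl.shape[0] < 3:
        raise ValueError("need at least 3 centerlines")
    if cl.shape[1] != s.size:
        raise ValueError("centerlines and arc_positions disagree on arc grid")
    (x0, y0), (x1, y1) = head_axis
    u = np.array([x1 - x0, y1 - y0], dtype=float)
    norm = np.linalg.norm(u)
    if norm == 0:
        raise ValueError("head_axis points must be distinct")
    u /= norm
    dx = cl[..., 0] - x0
    dy = cl[..., 1] - y0
    signed = u[0] * dy - u[1] * dx  # (n_frames, n_arc)
    amp_above = np.maximum(signed, 0.0).max(axis=0)
    amp_below = np.maximum(-signed, 0.0).max(axis=0)
    return BeatEnvelope(arc_positions=s, amp_above=amp_above, amp_below=amp_below)


def asymmetry_index(env: BeatEnvelope) -> float:
    """Normalized-difference asymmetry of the beat envelope, in [0, 1].

    ``|AUC_above - AUC_below| / (AUC_above + AUC_below)`` with each AUC the
    trapezoidal area of the envelope half over arc length.  0 indicates
    perfect beat symmetry, 1 complete asymmetry.
    """
    auc_above = float(np.trapezoid(env.amp_above, env.arc_positions))
    auc_below = float(np.trapezoid(env.amp_below, env.arc_positions))
    total = auc_above + auc_below
    if total <= 0:
        raise ValueError("both envelope areas are zero")
    return abs(auc_above - auc_below) / total


def max_amplitude(env: BeatEnvelope) -> float:
    """Maximal beat amplitude (um) over arc positions and both sides."""
    return float(np.maximum(env.amp_above, env.amp_below).max())
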