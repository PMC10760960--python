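"""Seeded generators for every input the analysis pipeline consumes.

Every generator is a pure function of its spec and seed: identical inputs
give bit-identical outputs.  The generators emulate

* head trajectories of progressive, hyperactive ("star-spin"), and immotile
  sperm at CASA recording conditions (80 fps, ~60 um chamber),
* exponential motility decay in Ca2+-free buffer with binomial counting
  noise,
* tethered-sperm angle traces (linear rotation ramp + sinusoidal beat
  oscillation + Gaussian noise) at 135 fps,
* flagellar beat envelopes with a controllable above/below-axis area ratio,
* screening cohorts with distinct donor and defective CAI ranges,
* mono- and biphasic Ca2+ responses normalized to an ionomycin maximum, and
* dark-field image stacks with Gaussian head spots (heads only; flagella
  are not rendered — flagellar analysis consumes centerlines directly).

The hyperactive trajectory model is a slow circular drift carrying a
large-amplitude lateral oscillation; its default parameters are frozen such
that the analyzed track satisfies the hyperactivation gate (VCL >= 150
um/s, LIN <= 0.5, ALH >= 7 um) at 80 fps, while the progressive defaults
fail it.  The gate itself is the only quantitative constraint on the
trajectory classes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .catsper import MotilityTimeSeries
from .flagbeat import AngleTrace, BeatEnvelope
from .signals import CalciumTrace
from .trackkin import ImageStack, Track

__all__ = [
    "TrackSpec",
    "DecaySpec",
    "BeatSpec",
    "EnvelopeSpec",
    "CohortSpec",
    "CalciumSpec",
    "CohortRecord",
    "Cohort",
    "PROGRESSIVE_SPEC",
    "HYPERACTIVE_SPEC",
    "IMMOTILE_SPEC",
    "gen_track",
    "gen_population",
    "gen_decay_series",
    "gen_angle_trace",
    "gen_envelope",
    "render_darkfield",
    "gen_cohort",
    "gen_calcium_trace",
    "gen_kinetic_ensemble",
]

TRACK_KINDS = ("progressive", "hyperactive", "immotile")

#: Arc length (um) of the synthetic flagellum used for envelope grids.
FLAGELLUM_LENGTH_UM = 50.0


def _require(cond: bool, fieldname: str, message: str) -> None:
    if not cond:
        raise ValueError(f"{fieldname}: {message}")


@dataclass(frozen=True)
class TrackSpec:
    """Generative parameters of one trajectory class."""

    kind: str
    speed: float  # um/s, forward drift speed of the path centre
    beat_freq: float  # Hz, lateral head oscillation
    lateral_amp: float  # um, lateral oscillation amplitude
    curvature_bias: float  # 1/um, signed path curvature of the drift
    duration: float = 1.0  # s
    frame_rate: float = 80.0  # frames/s
    noise_sd: float = 0.2  # um, isotropic localization jitter

    def __post_init__(self) -> None:
        _require(self.kind in TRACK_KINDS, "kind", f"must be one of {TRACK_KINDS}")
        _require(self.speed >= 0, "speed", "must be >= 0")
        _require(self.frame_rate > 0, "frame_rate", "must be > 0")
        _require(self.duration > 0, "duration", "must be > 0")
        _require(self.lateral_amp >= 0, "lateral_amp", "must be >= 0")
        _require(self.beat_freq >= 0, "beat_freq", "must be >= 0")
        _require(self.noise_sd >= 0, "noise_sd", "must be >= 0")


# Defaults frozen against the hyperactivation gate (see module docstring):
# the hyperactive class passes VCL/LIN/ALH with wide margins, the
# progressive class fails on LIN and ALH, and the immotile class stays
# below the 10 um/s motility threshold.
PROGRESSIVE_SPEC = TrackSpec(
    kind="progressive", speed=100.0, beat_freq=10.0, lateral_amp=1.0,
    curvature_bias=0.0, noise_sd=0.2,
)
HYPERACTIVE_SPEC = TrackSpec(
    kind="hyperactive", speed=30.0, beat_freq=16.0, lateral_amp=9.0,
    curvature_bias=0.21, noise_sd=0.2,
)
IMMOTILE_SPEC = TrackSpec(
    kind="immotile", speed=0.0, beat_freq=0.0, lateral_amp=0.0,
    curvature_bias=0.0, noise_sd=0.03,
)

DEFAULT_SPECS = {
    "progressive": PROGRESSIVE_SPEC,
    "hyperactive": HYPERACTIVE_SPEC,
    "immotile": IMMOTILE_SPEC,
}


@dataclass(frozen=True)
class DecaySpec:
    """Exponential motility-decay experiment in Ca2+-free buffer."""

    tau: float  # min; math.inf means no decay (control buffer)
    sample_times: tuple[float, ...] = tuple(range(0, 65, 5))  # min
    n_cells_per_timepoint: int | None = 200  # None: noiseless curve
    initial_motile: float = 100.0  # %

    def __post_init__(self) -> None:
        object.__setattr__(self, "sample_times", tuple(self.sample_times))
        _require(self.tau > 0, "tau", "must be > 0 (use math.inf for no decay)")
        st = np.asarray(self.sample_times, dtype=float)
        _require(st.size >= 1 and st[0] == 0, "sample_times", "must start at 0")
        _require(bool(np.all(np.diff(st) > 0)), "sample_times", "must be strictly increasing")
        _require(bool(np.all(st >= 0)), "sample_times", "must be non-negative")
        if self.n_cells_per_timepoint is not None:
            _require(self.n_cells_per_timepoint > 0, "n_cells_per_timepoint", "must be > 0")
        _require(0 < self.initial_motile <= 100, "initial_motile", "must lie in (0, 100]")


@dataclass(frozen=True)
class BeatSpec:
    """Tethered-sperm angle trace: rotation ramp + sinusoidal oscillation."""

    osc_freq: float = 15.0  # Hz
    osc_amp: float = 10.0  # deg
    rotation_velocity: float = 50.0  # deg/s
    phase: float | None = None  # rad; None: drawn uniformly per seed
    noise_sd: float = 2.0  # deg
    duration: float = 15.0  # s
    frame_rate: float = 135.0  # frames/s

    def __post_init__(self) -> None:
        _require(self.osc_freq >= 0, "osc_freq", "must be >= 0")
        _require(self.duration > 0, "duration", "must be > 0")
        _require(self.noise_sd >= 0, "noise_sd", "must be >= 0")
        _require(
            self.frame_rate > 2 * self.osc_freq,
            "frame_rate",
            "must exceed twice osc_freq (oscillation unresolvable otherwise)",
        )


@dataclass(frozen=True)
class EnvelopeSpec:
    """Beat envelope with prescribed areas above and below the head axis."""

    area_above: float  # um^2 (amplitude x arc length)
    area_below: float  # um^2
    n_arc_points: int = 64
    profile_shape: str = "sinusoidal"  # or "triangular"

    def __post_init__(self) -> None:
        _require(self.area_above >= 0, "area_above", "must be >= 0")
        _require(self.area_below >= 0, "area_below", "must be >= 0")
        _require(
            self.area_above + self.area_below > 0,
            "area_above/area_below", "cannot both be zero",
        )
        _require(self.n_arc_points >= 3, "n_arc_points", "must be >= 3")
        _require(
            self.profile_shape in ("sinusoidal", "triangular"),
            "profile_shape", "must be 'sinusoidal' or 'triangular'",
        )


@dataclass(frozen=True)
class CohortSpec:
    """Screening cohort: donors plus a known number of defective subjects."""

    n_subjects: int
    n_defective: int
    donor_cai_range: tuple[float, float] = (70.0, 100.0)
    defective_cai_range: tuple[float, float] = (0.0, 40.0)
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_subjects >= 1, "n_subjects", "must be >= 1")
        _require(
            0 <= self.n_defective <= self.n_subjects,
            "n_defective", "must lie in [0, n_subjects]",
        )
        for name in ("donor_cai_range", "defective_cai_range"):
            lo, hi = getattr(self, name)
            _require(0 <= lo <= hi <= 100, name, "must satisfy 0 <= lo <= hi <= 100")


@dataclass(frozen=True)
class CalciumSpec:
    """Stimulus-evoked Ca2+ response followed by an ionomycin maximum."""

    baseline: float = 200.0  # a.u.
    response_amp: float = 0.5  # fraction of the ionomycin amplitude
    waveform: str = "biphasic"  # or "monophasic"
    iono_amp: float = 400.0  # a.u.
    noise_sd: float = 0.0  # a.u.
    frame_rate: float = 2.0  # frames/s
    stim_time: float = 30.0  # s
    iono_time: float = 180.0  # s
    post_iono: float = 60.0  # s recorded after ionomycin

    def __post_init__(self) -> None:
        _require(self.baseline > 0, "baseline", "must be > 0")
        _require(self.iono_amp > 0, "iono_amp", "must be > 0")
        _require(self.response_amp >= 0, "response_amp", "must be >= 0")
        _require(self.stim_time < self.iono_time, "stim_time", "must precede iono_time")
        _require(self.stim_time > 0, "stim_time", "must be > 0")
        _require(self.frame_rate > 0, "frame_rate", "must be > 0")
        _require(self.noise_sd >= 0, "noise_sd", "must be >= 0")
        _require(self.waveform in ("biphasic", "monophasic"), "waveform", "invalid")


@dataclass(frozen=True)
class CohortRecord:
    """One screened subject with its ground-truth label."""

    subject_id: str
    cai: float
    defective: bool  # ground truth, retained for validation


@dataclass(frozen=True)
class Cohort:
    records: tuple[CohortRecord, ...]
    metadata: dict = field(default_factory=dict)


def gen_track(spec: TrackSpec, seed: int, track_id: str | None = None) -> Track:
    """Generate one head trajectory of the given class.

    The path centre drifts at ``speed`` along a heading that turns at rate
    ``speed * curvature_bias`` (rad/s); the head oscillates laterally with
    amplitude ``lateral_amp`` at ``beat_freq``; isotropic Gaussian jitter of
    ``noise_sd`` is added to every position.  Initial heading and beat
    phase are drawn from the seeded generator, so tracks differ between
    seeds but are bit-reproducible for a fixed (spec, seed).
    """
    rng = np.random.default_rng(seed)
    n = int(round(spec.duration * spec.frame_rate)) + 1
    t = np.arange(n) / spec.frame_rate
    psi0 = rng.uniform(0, 2 * np.pi)
    phase = rng.uniform(0, 2 * np.pi)
    if spec.kind == "immotile":
        cx = np.zeros(n)
        cy = np.zeros(n)
        psi = np.full(n, psi0)
    else:
        turn_rate = spec.speed * spec.curvature_bias  # rad/s
        psi = psi0 + turn_rate * t
        if abs(turn_rate) < 1e-12:
            cx = spec.speed * t * np.cos(psi0)
            cy = spec.speed * t * np.sin(psi0)
        else:
            # closed form for constant-curvature drift (circle of radius v/omega)
            r = spec.speed / turn_rate
            cx = r * (np.sin(psi) - np.sin(psi0))
            cy = -r * (np.cos(psi) - np.cos(psi0))
    lateral = spec.lateral_amp * np.sin(2 * np.pi * spec.beat_freq * t + phase)
    x = cx + lateral * (-np.sin(psi))
    y = cy + lateral * np.cos(psi)
    if spec.noise_sd > 0:
        x = x + rng.normal(0, spec.noise_sd, n)
        y = y + rng.normal(0, spec.noise_sd, n)
    return Track(
        track_id=track_id or f"{spec.kind}_{seed}",
        t=t, x=x, y=y, frame_rate=spec.frame_rate,
    )


def _largest_remainder_counts(n: int, mixture: dict[str, float]) -> dict[str, int]:
    total = sum(mixture.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"mixture fractions sum to {total}, not 1")
    quotas = {k: n * f for k, f in mixture.items()}
    counts = {k: int(math.floor(q)) for k, q in quotas.items()}
    short = n - sum(counts.values())
    # distribute leftovers by largest fractional remainder; ties broken by
    # mixture insertion order (stable sort)
    order = sorted(mixture, key=lambda k: quotas[k] - counts[k], reverse=True)
    for k in order[:short]:
        counts[k] += 1
    return counts


def gen_population(
    n: int,
    mixture: dict[str, float],
    specs: dict[str, TrackSpec] | None = None,
    seed: int = 0,
) -> tuple[list[Track], dict[str, int]]:
    """Generate a mixed population of ``n`` tracks.

    Class counts are ``round(n * fraction)`` with largest-remainder
    rounding (ties by mixture order), so they are exact and sum to ``n``.
    Returns the tracks (class recorded in each ``track_id``) and the
    per-class counts.
    """
    if specs is None:
        specs = DEFAULT_SPECS
    counts = _largest_remainder_counts(n, mixture)
    child_seeds = np.random.SeedSequence(seed).generate_state(n)
    tracks: list[Track] = []
    i = 0
    for kind, count in counts.items():
        spec = specs[kind]
        for j in range(count):
            tracks.append(
                gen_track(spec, int(child_seeds[i]), track_id=f"{kind}_{j:04d}")
            )
            i += 1
    return tracks, counts


def gen_decay_series(spec: DecaySpec, seed: int = 0, condition: str = "HTF0Ca") -> MotilityTimeSeries:
    """Motility-decay observations from exponential survival.

    The motile fraction at time t is ``binomial(n_cells, p(t)) * 100 /
    n_cells`` with ``p(t) = (initial_motile/100) * exp(-t/tau)`` — counting
    noise on a counted fraction.  ``n_cells_per_timepoint=None`` returns the
    noiseless curve; ``tau = inf`` returns the constant initial fraction.
    """
    t = np.asarray(spec.sample_times, dtype=float)
    if math.isinf(spec.tau):
        surv = np.ones_like(t)
    else:
        surv = np.exp(-t / spec.tau)
    p = (spec.initial_motile / 100.0) * surv
    if spec.n_cells_per_timepoint is None:
        frac = 100.0 * p
    else:
        rng = np.random.default_rng(seed)
        n_cells = spec.n_cells_per_timepoint
        frac = 100.0 * rng.binomial(n_cells, p) / n_cells
    return MotilityTimeSeries(
        condition=condition, times=t, motile_fraction=frac,
        n_cells=spec.n_cells_per_timepoint,
    )


def gen_angle_trace(spec: BeatSpec, seed: int = 0, epoch: str = "pre") -> AngleTrace:
    """Tethered-sperm angle trace theta(t) = Omega*t + A*sin(2*pi*f*t + phi) + noise.

    Returned unwrapped (no 360-degree jumps).  ``spec.phase=None`` draws the
    phase from the seeded generator; the Gaussian noise uses the same
    generator, so a (spec, seed) pair is fully reproducible.
    """
    rng = np.random.default_rng(seed)
    phase = rng.uniform(0, 2 * np.pi) if spec.phase is None else spec.phase
    n = int(round(spec.duration * spec.frame_rate)) + 1
    t = np.arange(n) / spec.frame_rate
    theta = spec.rotation_velocity * t + spec.osc_amp * np.sin(
        2 * np.pi * spec.osc_freq * t + phase
    )
    if spec.noise_sd > 0:
        theta = theta + rng.normal(0, spec.noise_sd, n)
    theta = theta - theta[0]
    return AngleTrace(times=t, theta=theta, frame_rate=spec.frame_rate, epoch=epoch)


def gen_envelope(spec: EnvelopeSpec) -> BeatEnvelope:
    """Beat envelope whose trapezoidal areas match the spec exactly.

    Both sides share an arc grid over a 50-um flagellum; each side is a
    unit profile (half-sine or triangle peaking mid-flagellum) scaled so
    its trapezoidal area equals the requested area to within 1e-9 relative.
    """
    s = np.linspace(0.0, FLAGELLUM_LENGTH_UM, spec.n_arc_points)
    if spec.profile_shape == "sinusoidal":
        unit = np.sin(np.pi * s / FLAGELLUM_LENGTH_UM)
    else:
        unit = 1.0 - np.abs(2.0 * s / FLAGELLUM_LENGTH_UM - 1.0)
    unit_area = float(np.trapezoid(unit, s))
    amp_above = unit * (spec.area_above / unit_area)
    amp_below = unit * (spec.area_below / unit_area)
    return BeatEnvelope(arc_positions=s, amp_above=amp_above, amp_below=amp_below)


def render_darkfield(
    tracks: list[Track],
    image_shape: tuple[int, int] = (256, 256),
    psf_sigma: float = 2.0,
    background: float = 100.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    pixel_size: float = 1.0,
    amplitude: float = 2000.0,
) -> ImageStack:
    """Render head trajectories as Gaussian spots on a noisy background.

    One frame per time point; all tracks must share their time base and fit
    in the field of view after um -> px conversion.  Only heads are
    rendered.  Intensities are clipped at zero so the stack is
    uint16-writable.
    """
    if not tracks:
        raise ValueError("empty track list")
    n_frames = tracks[0].n_points
    frame_rate = tracks[0].frame_rate
    for tr in tracks:
        if tr.n_points != n_frames or abs(tr.frame_rate - frame_rate) > 1e-9:
            raise ValueError("all tracks must share length and frame rate")
    rows, cols = image_shape
    for tr in tracks:
        px = tr.x / pixel_size
        py = tr.y / pixel_size
        if px.min() < 0 or py.min() < 0 or px.max() >= cols or py.max() >= rows:
            raise ValueError(
                f"track {tr.track_id} leaves the {rows}x{cols} px field of view"
            )
    rng = np.random.default_rng(seed)
    frames = np.full((n_frames, rows, cols), background, dtype=float)
    half = int(math.ceil(4 * psf_sigma))
    for tr in tracks:
        px = tr.x / pixel_size
        py = tr.y / pixel_size
        for fi in range(n_frames):
            c0, r0 = px[fi], py[fi]
            rlo = max(int(r0) - half, 0)
            rhi = min(int(r0) + half + 1, rows)
            clo = max(int(c0) - half, 0)
            chi = min(int(c0) + half + 1, cols)
            rr, cc = np.mgrid[rlo:rhi, clo:chi]
            frames[fi, rlo:rhi, clo:chi] += amplitude * np.exp(
                -((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * psf_sigma**2)
            )
    if noise_sd > 0:
        frames = frames + rng.normal(0, noise_sd, frames.shape)
    frames = np.clip(frames, 0, None)
    return ImageStack(frames=frames, frame_rate=frame_rate, pixel_size=pixel_size)


def gen_cohort(spec: CohortSpec, threshold: float = 40.0) -> Cohort:
    """Screening cohort with uniform CAI draws per group.

    Defective subjects' CAI is uniform over ``defective_cai_range``, donors'
    over ``donor_cai_range``; subject order is shuffled.  If either range
    straddles the screening threshold, a warning is recorded in the cohort
    metadata (labels remain the ground truth).
    """
    rng = np.random.default_rng(spec.seed)
    n_don = spec.n_subjects - spec.n_defective
    cais = np.concatenate(
        [
            rng.uniform(*spec.defective_cai_range, spec.n_defective),
            rng.uniform(*spec.donor_cai_range, n_don),
        ]
    )
    labels = np.concatenate(
        [np.ones(spec.n_defective, dtype=bool), np.zeros(n_don, dtype=bool)]
    )
    order = rng.permutation(spec.n_subjects)
    records = tuple(
        CohortRecord(
            subject_id=f"subject_{i:05d}", cai=float(cais[j]), defective=bool(labels[j])
        )
        for i, j in enumerate(order)
    )
    metadata: dict = {"seed": spec.seed, "threshold": threshold, "warnings": []}
    if spec.n_defective and spec.defective_cai_range[1] > threshold:
        metadata["warnings"].append("defective CAI range extends above the threshold")
    if n_don and spec.donor_cai_range[0] <= threshold:
        metadata["warnings"].append("donor CAI range extends to or below the threshold")
    return Cohort(records=records, metadata=metadata)


def gen_kinetic_ensemble(
    hyper_frac_per_window: list[float],
    scheme=None,
    n_per_window: int = 500,
    n_subwindows: int = 3,
    subwindow_len: float = 1.0,
    seed: int = 0,
    specs: dict[str, TrackSpec] | None = None,
) -> list[Track]:
    """Track ensemble for a rapid-mixing (kinetic CASA) experiment.

    Per analysis window, ``n_per_window`` one-second tracks are generated
    and spread round-robin over the window's evenly placed sub-interval
    start times; the share of hyperactive tracks equals the requested
    per-window fraction exactly (largest-remainder rounding, the same
    policy as :func:`gen_population`), with the remainder progressive.
    Randomness enters through the individual trajectories (heading, phase,
    localization noise), not the class composition.
    """
    from .kinetics import default_scheme  # deferred: kinetics imports trackkin only

    if scheme is None:
        scheme = default_scheme()
    if len(hyper_frac_per_window) != len(scheme.windows):
        raise ValueError("need one hyperactive fraction per window")
    if specs is None:
        specs = DEFAULT_SPECS
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(n_per_window * len(scheme.windows))
    rng = np.random.default_rng(ss.spawn(1)[0])
    tracks: list[Track] = []
    i = 0
    for (start, end), h in zip(scheme.windows, hyper_frac_per_window):
        if not 0 <= h <= 100:
            raise ValueError("hyperactive fractions must lie in [0, 100]")
        counts = _largest_remainder_counts(
            n_per_window, {"hyperactive": h / 100.0, "progressive": 1.0 - h / 100.0}
        )
        kinds = ["hyperactive"] * counts["hyperactive"] + (
            ["progressive"] * counts["progressive"]
        )
        rng.shuffle(kinds)
        if n_subwindows == 1:
            starts = np.array([start])
        else:
            starts = np.linspace(start, end - subwindow_len, n_subwindows)
        for j, kind in enumerate(kinds):
            spec = replace(
                specs[kind], duration=subwindow_len, frame_rate=specs[kind].frame_rate
            )
            base = gen_track(spec, int(child_seeds[i]), track_id=f"w{start:g}_{kind}_{j:04d}")
            s0 = float(starts[j % len(starts)])
            tracks.append(
                Track(
                    track_id=base.track_id,
                    t=base.t + s0, x=base.x, y=base.y,
                    frame_rate=base.frame_rate,
                )
            )
            i += 1
    return tracks


def _biphasic_shape(u: np.ndarray) -> np.ndarray:
    fast = (1.0 - np.exp(-u / 0.3)) * np.exp(-u / 5.0)
    sustained = 0.5 * np.exp(-(((u - 25.0) / 10.0) ** 2))
    shape = fast + sustained
    return shape


def _monophasic_shape(u: np.ndarray) -> np.ndarray:
    return np.exp(-(((u - 20.0) / 12.0) ** 2))


def gen_calcium_trace(spec: CalciumSpec, seed: int = 0, source: str = "population") -> CalciumTrace:
    """Fluorescence trace: baseline, stimulus response, ionomycin maximum.

    The stimulus segment is a unit-peak waveform (biphasic: fast transient
    plus a delayed sustained component; monophasic: one slow rise) scaled to
    ``response_amp * iono_amp``; ionomycin drives a rapid saturating step of
    amplitude ``iono_amp``.  With zero noise, normalizing the stimulus peak
    to the ionomycin maximum recovers ``response_amp`` by construction.
    """
    rng = np.random.default_rng(seed)
    total = spec.iono_time + spec.post_iono
    n = int(round(total * spec.frame_rate)) + 1
    t = np.arange(n) / spec.frame_rate
    f = np.full(n, spec.baseline, dtype=float)
    u = t - spec.stim_time
    stim_mask = (u >= 0) & (t < spec.iono_time)
    if spec.response_amp > 0 and np.any(stim_mask):
        shape_fn = _biphasic_shape if spec.waveform == "biphasic" else _monophasic_shape
        shape = shape_fn(u[stim_mask])
        shape = shape / shape.max()
        f[stim_mask] += spec.response_amp * spec.iono_amp * shape
    v = t - spec.iono_time
    iono_mask = v >= 0
    f[iono_mask] += spec.iono_amp * (1.0 - np.exp(-v[iono_mask] / 1.0))
    if spec.noise_sd > 0:
        f = f + rng.normal(0, spec.noise_sd, n)
    f = np.clip(f, 1e-9, None)
    return CalciumTrace(
        times=t, F=f,
        events=(("stimulus", spec.stim_time), ("ionomycin", spec.iono_time)),
        source=source,
    )
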