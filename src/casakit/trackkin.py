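"""Computer-assisted sperm analysis (CASA) on head trajectories.

The front end detects sperm heads in dark-field image stacks and links the
per-frame centroids into trajectories.  The back end computes the standard
CASA kinematic parameters per trajectory — curvilinear (VCL), straight-line
(VSL), and average-path (VAP) velocities, amplitude of lateral head
displacement (ALH), beat-cross frequency (BCF), and the path-shape ratios
LIN = VSL/VCL, STR = VSL/VAP, WOB = VAP/VCL — and classifies tracks as
motile and as hyperactive.

Hyperactivation is gated on VCL >= 150 um/s, LIN <= 0.5, and ALH >= 7 um
(boundaries inclusive), the criteria in routine use for human sperm.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

__all__ = [
    "Track",
    "KinematicSummary",
    "ImageStack",
    "HyperactivationGate",
    "detect_heads",
    "link_tracks",
    "vap_path",
    "kinematics",
    "classify_hyperactive",
    "motile_fraction",
    "analyze_stack",
]

#: Default VCL threshold (um/s) below which a track is considered immotile.
MOTILE_VCL_MIN = 10.0


@dataclass(frozen=True)
class HyperactivationGate:
    """Kinematic gate for hyperactive motility (all boundaries inclusive)."""

    vcl_min: float = 150.0  # um/s
    lin_max: float = 0.5
    alh_min: float = 7.0  # um

    def passes(self, vcl: float, lin: float, alh: float) -> bool:
        return vcl >= self.vcl_min and lin <= self.lin_max and alh >= self.alh_min


DEFAULT_GATE = HyperactivationGate()


@dataclass(frozen=True)
class Track:
    """Time-stamped 2-D head-position series in micrometres.

    Timestamps must be strictly increasing and uniformly spaced (within
    1 us); at least two points are required.
    """

    track_id: str
    t: np.ndarray  # s
    x: np.ndarray  # um
    y: np.ndarray  # um
    frame_rate: float  # frames/s
    pixel_size: float = 1.0  # um/px provenance of the source images

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if t.ndim != 1 or t.size < 2:
            raise ValueError("Track requires at least 2 points")
        if not (len(t) == len(x) == len(y)):
            raise ValueError("t, x, y must have equal length")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if np.ptp(dt) > 1e-6:
            raise ValueError("timestamps must be uniformly spaced (within 1e-6 s)")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_points(self) -> int:
        return int(self.t.size)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def xy(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])


@dataclass(frozen=True)
class KinematicSummary:
    """Per-track CASA kinematic parameters and classification flags.

    ``str_`` is the straightness STR = VSL/VAP (trailing underscore avoids
    shadowing the builtin).
    """

    vcl: float  # um/s
    vsl: float  # um/s
    vap: float  # um/s
    alh: float  # um
    bcf: float  # Hz
    lin: float
    str_: float
    wob: float
    motile: bool
    hyperactive: bool

    def __post_init__(self) -> None:
        if self.vsl > self.vcl + 1e-9 or self.vap > self.vcl + 1e-9:
            raise ValueError("VSL and VAP cannot exceed VCL")
        for name in ("lin", "wob"):
            v = getattr(self, name)
            if not (-1e-9 <= v <= 1 + 1e-9):
                raise ValueError(f"{name.upper()} must lie in [0, 1]")
        if self.alh < 0 or self.bcf < 0 or self.str_ < 0:
            raise ValueError("ALH, BCF, STR must be non-negative")


@dataclass(frozen=True)
class ImageStack:
    """Dark-field time-lapse: (frame, row, col) intensities with calibration."""

    frames: np.ndarray
    frame_rate: float  # frames/s
    pixel_size: float  # um/px

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames)
        object.__setattr__(self, "frames", frames)
        if frames.ndim != 3 or frames.shape[0] < 1:
            raise ValueError("frames must be a 3-D array with >= 1 frame")
        if np.any(frames < 0):
            raise ValueError("intensities must be non-negative")
        if self.frame_rate <= 0 or self.pixel_size <= 0:
            raise ValueError("frame_rate and pixel_size must be positive")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])


def detect_heads(
    frame: np.ndarray,
    threshold_mode: str = "otsu",
    min_area: int = 1,
    pixel_size: float = 1.0,
    fixed_threshold: float | None = None,
) -> list[tuple[float, float]]:
    """Detect bright sperm heads in one frame.

    Returns intensity-weighted centroids ``(x, y)`` in micrometres of
    connected components above threshold with area >= ``min_area`` px^2.
    A constant frame yields an empty list.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("frame must be 2-D")
    if not np.all(np.isfinite(frame)):
        raise ValueError("frame contains non-finite values")
    if np.ptp(frame) == 0:
        return []
    if threshold_mode == "otsu":
        thr = threshold_otsu(frame)
    elif threshold_mode == "fixed":
        if fixed_threshold is None:
            raise ValueError("fixed_threshold required for threshold_mode='fixed'")
        thr = fixed_threshold
    else:
        raise ValueError(f"unknown threshold_mode {threshold_mode!r}")
    mask = frame > thr
    labels = label(mask)
    out: list[tuple[float, float]] = []
    for region in regionprops(labels, intensity_image=frame):
        if region.area < min_area:
            continue
        row, col = region.centroid_weighted
        out.append((col * pixel_size, row * pixel_size))
    return out


def link_tracks(
    detections: list[list[tuple[float, float]]],
    max_disp: float,
    frame_rate: float,
    pixel_size: float = 1.0,
) -> list[Track]:
    """Link per-frame centroids into tracks by greedy mutual nearest neighbours.

    A track and a detection are linked only if each is the other's nearest
    candidate and their distance is <= ``max_disp`` (um).  Unmatched
    detections seed new tracks; a track missing a detection in any frame is
    terminated (no gap closing).  Tracks shorter than 2 points are dropped.
    """
    if max_disp <= 0:
        raise ValueError("max_disp must be positive")
    if len(detections) < 2:
        raise ValueError("need detections for at least 2 frames")
    active: list[dict] = []  # each: {"frames": [...], "pts": [...]}
    finished: list[dict] = []
    for fi, dets in enumerate(detections):
        pts = np.asarray(dets, dtype=float).reshape(-1, 2)
        if fi == 0:
            active = [{"frames": [0], "pts": [p]} for p in pts]
            continue
        links: dict[int, int] = {}
        if active and len(pts):
            last = np.array([tr["pts"][-1] for tr in active])
            dist = np.linalg.norm(last[:, None, :] - pts[None, :, :], axis=2)
            nn_det = dist.argmin(axis=1)  # nearest detection per track
            nn_trk = dist.argmin(axis=0)  # nearest track per detection
            for ti, di in enumerate(nn_det):
                if nn_trk[di] == ti and dist[ti, di] <= max_disp:
                    links[ti] = int(di)
        still_active = []
        for ti, tr in enumerate(active):
            if ti in links:
                tr["frames"].append(fi)
                tr["pts"].append(pts[links[ti]])
                still_active.append(tr)
            else:
                finished.append(tr)
        linked = set(links.values())
        for di in range(len(pts)):
            if di not in linked:
                still_active.append({"frames": [fi], "pts": [pts[di]]})
        active = still_active
    finished.extend(active)
    tracks: list[Track] = []
    for k, tr in enumerate(finished):
        if len(tr["frames"]) < 2:
            continue
        frames = np.asarray(tr["frames"], dtype=float)
        pts = np.asarray(tr["pts"], dtype=float)
        tracks.append(
            Track(
                track_id=f"track_{k:04d}",
                t=frames / frame_rate,
                x=pts[:, 0],
                y=pts[:, 1],
                frame_rate=frame_rate,
                pixel_size=pixel_size,
            )
        )
    return tracks


def vap_path(track: Track, window: int) -> np.ndarray:
    """Centred moving average of the head positions (the VAP path).

    ``window`` must be odd.  Near the ends the window shrinks symmetrically
    (half-width ``min(i, n-1-i, window//2)``) so it stays centred, the
    smoothed path keeps the track's endpoints, and a straight track is
    smoothing-invariant.  Returns an ``(n, 2)`` array of ``(x, y)`` in um.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    n = track.n_points
    if window > n:
        raise ValueError("window exceeds track length")
    xy = track.xy()
    half = window // 2
    out = np.empty_like(xy)
    for i in range(n):
        h = min(i, n - 1 - i, half)
        out[i] = xy[i - h : i + h + 1].mean(axis=0)
    return out


def _signed_lateral_deviation(xy: np.ndarray, smooth: np.ndarray) -> np.ndarray:
    """Signed perpendicular distance of the head from the VAP path.

    The sign is the z-component of the cross product of the local VAP-path
    tangent with the deviation vector; points where the tangent vanishes get
    deviation magnitude with sign 0.
    """
    tangent = np.gradient(smooth, axis=0)
    norms = np.linalg.norm(tangent, axis=1)
    dev = xy - smooth
    signed = np.empty(len(xy))
    ok = norms > 1e-12
    signed[ok] = (
        tangent[ok, 0] * dev[ok, 1] - tangent[ok, 1] * dev[ok, 0]
    ) / norms[ok]
    signed[~ok] = 0.0
    return signed


def kinematics(
    track: Track,
    vap_window: int = 5,
    motile_vcl_min: float = MOTILE_VCL_MIN,
    alh_factor: float = 2.0,
    gate: HyperactivationGate = DEFAULT_GATE,
) -> KinematicSummary:
    """Compute the CASA kinematic summary of one track.

    * VCL: summed frame-to-frame distances / duration.
    * VSL: first-to-last distance / duration.
    * VAP: arc length of the ``vap_window``-frame moving-average path /
      duration.
    * ALH: ``alh_factor`` x mean absolute lateral deviation of the head
      from the VAP path (factor 2 approximates the peak-to-peak convention).
    * BCF: number of sign changes of the lateral deviation / duration.

    A track with VCL = 0 gets all ratios defined as 0 and both flags false.
    """
    vap_window = min(vap_window, track.n_points if track.n_points % 2 == 1 else track.n_points - 1)
    duration = track.duration
    if duration <= 0:
        raise ValueError("zero-duration track")
    xy = track.xy()
    steps = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    vcl = float(steps.sum() / duration)
    vsl = float(np.linalg.norm(xy[-1] - xy[0]) / duration)
    smooth = vap_path(track, vap_window)
    vap = float(np.linalg.norm(np.diff(smooth, axis=0), axis=1).sum() / duration)
    if vcl == 0.0:
        return KinematicSummary(0, 0, 0, 0, 0, 0, 0, 0, motile=False, hyperactive=False)
    lin = min(vsl / vcl, 1.0)
    wob = min(vap / vcl, 1.0)
    str_ = vsl / vap if vap > 0 else 0.0
    signed = _signed_lateral_deviation(xy, smooth)
    alh = float(alh_factor * np.mean(np.abs(signed)))
    signs = np.sign(signed)
    signs = signs[signs != 0]
    bcf = float(np.count_nonzero(np.diff(signs) != 0) / duration)
    motile = vcl >= motile_vcl_min
    hyper = gate.passes(vcl, lin, alh)
    return KinematicSummary(vcl, vsl, vap, alh, bcf, lin, str_, wob, motile, hyper)


def classify_hyperactive(ks: KinematicSummary, gate: HyperactivationGate = DEFAULT_GATE) -> bool:
    """True iff VCL >= 150 um/s AND LIN <= 0.5 AND ALH >= 7 um (inclusive)."""
    for v in (ks.vcl, ks.lin, ks.alh):
        if not np.isfinite(v):
            raise ValueError("kinematic summary contains non-finite values")
    return gate.passes(ks.vcl, ks.lin, ks.alh)


def motile_fraction(
    tracks: list[Track],
    motile_vcl_min: float = MOTILE_VCL_MIN,
    vap_window: int = 5,
) -> float:
    """Percent of tracks with VCL >= ``motile_vcl_min``."""
    if not tracks:
        raise ValueError("empty track list")
    n_motile = sum(
        kinematics(tr, vap_window=vap_window, motile_vcl_min=motile_vcl_min).motile
        for tr in tracks
    )
    return 100.0 * n_motile / len(tracks)


def analyze_stack(
    stack: ImageStack,
    max_disp: float,
    threshold_mode: str = "otsu",
    min_area: int = 1,
    fixed_threshold: float | None = None,
) -> list[Track]:
    """Detect heads in every frame of a stack and link them into tracks."""
    detections = [
        detect_heads(
            fr,
            threshold_mode=threshold_mode,
            min_area=min_area,
            pixel_size=stack.pixel_size,
            fixed_threshold=fixed_threshold,
        )
        for fr in stack.frames
    ]
    return link_tracks(
        detections, max_disp=max_disp, frame_rate=stack.frame_rate, pixel_size=stack.pixel_size
    )


def summaries_frame(summaries: list[KinematicSummary], track_ids: list[str] | None = None):
    """Tabulate kinematic summaries as a pandas DataFrame (one row per track)."""
    import pandas as pd

    rows = [dataclasses.asdict(s) for s in summaries]
    df = pd.DataFrame(rows)
    if track_ids is not None:
        df.insert(0, "track_id", track_ids)
    return df
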