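"""The CatSper-Activity-Test: motility decay, activity index, cohort screening.

Diluting human sperm in Ca2+-free buffer arrests their motility; the arrest
requires the sperm-specific Ca2+ channel CatSper and is accelerated by the
CatSper agonist progesterone.  The test contrasts the fraction of motile
sperm after dilution in control buffer (Buffer A) against dilution in
Ca2+-free, progesterone-fortified buffer (Buffer B):

* :func:`fit_decay` fits the one-phase decay ``Y(t) = 100 * exp(-t / tau)``
  (initial motile fraction constrained to 100 %) to a motility time series.
* :func:`compute_cai` derives the CatSper-Activity-Index
  ``CAI = 100 * (1 - M_B / M_A)``, clamped to [0, 100].  With normal CatSper
  function, Buffer B arrests motility and the CAI is high (donors span
  roughly 70-100); if CatSper is defective or pharmacologically inhibited,
  motility persists in Buffer B and the CAI is low.
* :func:`screen_cohort` flags subjects with CAI <= 40 (inclusive) as
  indicative of defective CatSper function.
* :func:`estimate_prevalence` converts an observed cohort frequency into a
  male-factor prevalence estimate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "MotilityTimeSeries",
    "DecayFit",
    "CAIRecord",
    "ScreeningReport",
    "fit_decay",
    "compute_cai",
    "cai_record",
    "screen_cohort",
    "estimate_prevalence",
    "CAI_THRESHOLD",
]

#: CAI at or below this value is flagged as indicative of defective CatSper.
CAI_THRESHOLD = 40.0

#: Minimum total motility (%) for the test to be applicable to a sample.
MIN_MOTILE_A = 10.0

_VALID_READOUTS = (15, 30, 60)


@dataclass(frozen=True)
class MotilityTimeSeries:
    """Motile fraction (%) observed over time (minutes) for one condition."""

    condition: str
    times: np.ndarray  # min
    motile_fraction: np.ndarray  # % in [0, 100]
    n_cells: int | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        f = np.asarray(self.motile_fraction, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "motile_fraction", f)
        if t.size != f.size:
            raise ValueError("times and motile_fraction must have equal length")
        if np.any(t < 0):
            raise ValueError("times must be non-negative")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any((f < 0) | (f > 100)):
            raise ValueError("motile_fraction must lie in [0, 100]")


@dataclass(frozen=True)
class DecayFit:
    """Result of the constrained one-phase decay fit.

    ``tau`` is in minutes; a series that does not decay is reported with
    ``tau = inf`` and ``converged = False``.  ``y0`` is fixed at 100 %.
    """

    tau: float
    rss: float
    converged: bool
    y0: float = 100.0
    plateau: float = 0.0


@dataclass(frozen=True)
class CAIRecord:
    """CatSper-Activity-Index of one subject."""

    subject_id: str
    motile_a: float  # % in Buffer A
    motile_b: float  # % in Buffer B
    readout_min: int
    cai: float
    flagged: bool


@dataclass(frozen=True)
class ScreeningReport:
    """Outcome of screening a cohort of CAI records against a threshold."""

    threshold: float
    n_total: int
    n_flagged: int
    fraction_flagged: float  # % of cohort
    flagged_ids: tuple[str, ...]


def _decay_model(t: np.ndarray, tau: float) -> np.ndarray:
    return 100.0 * np.exp(-t / tau)


def _decay_model_plateau(t: np.ndarray, tau: float, plateau: float) -> np.ndarray:
    return plateau + (100.0 - plateau) * np.exp(-t / tau)


def fit_decay(series: MotilityTimeSeries, fit_plateau: bool = False) -> DecayFit:
    """Least-squares fit of the one-phase motility decay.

    The model is ``Y(t) = 100 * exp(-t / tau)`` with the initial motile
    fraction constrained to 100 %.  ``fit_plateau=True`` instead fits
    ``Y(t) = P + (100 - P) * exp(-t / tau)`` for series that level off above
    zero (e.g. partial CatSper inhibition).

    The initial guess for tau comes from the first crossing of 50 %
    (tau0 = t_half / ln 2), falling back to half the series span.  A series
    with no net decrease is reported as non-converged with ``tau = inf``.
    """
    t = series.times
    y = series.motile_fraction
    if t.size < 3:
        raise ValueError("need at least 3 time points")
    if y[-1] >= y[0] - 1e-12:
        return DecayFit(tau=math.inf, rss=float(np.sum((y - y[0]) ** 2)), converged=False)
    below = np.nonzero(y < 50.0)[0]
    if below.size:
        tau0 = max(t[below[0]], t[1]) / math.log(2)
    else:
        tau0 = (t[-1] - t[0]) / 2
    tau0 = max(tau0, 1e-6)
    try:
        if fit_plateau:
            popt, _ = curve_fit(
                _decay_model_plateau,
                t,
                y,
                p0=[tau0, max(float(y[-1]), 0.0)],
                bounds=([1e-9, 0.0], [np.inf, 100.0]),
                maxfev=10000,
            )
            tau, plateau = float(popt[0]), float(popt[1])
            resid = y - _decay_model_plateau(t, tau, plateau)
        else:
            popt, _ = curve_fit(
                _decay_model, t, y, p0=[tau0], bounds=(1e-9, np.inf), maxfev=10000
            )
            tau, plateau = float(popt[0]), 0.0
            resid = y - _decay_model(t, tau)
    except RuntimeError:
        return DecayFit(tau=math.inf, rss=math.inf, converged=False)
    return DecayFit(tau=tau, rss=float(np.sum(resid**2)), converged=True, plateau=plateau)


def compute_cai(motile_a: float, motile_b: float) -> float:
    """CatSper-Activity-Index: ``100 * (1 - M_B / M_A)``, clamped to [0, 100].

    ``motile_a`` (control buffer) must be positive; samples below 10 % total
    motility are outside the test's validity range and raise a warning.
    """
    if motile_a <= 0:
        raise ValueError("motile fraction in Buffer A must be positive (test not applicable)")
    if motile_a < MIN_MOTILE_A:
        warnings.warn(
            f"Buffer-A motility {motile_a:.1f}% is below the {MIN_MOTILE_A:.0f}% "
            "applicability minimum",
            stacklevel=2,
        )
    if motile_b < 0:
        raise ValueError("motile fraction in Buffer B cannot be negative")
    cai = 100.0 * (1.0 - motile_b / motile_a)
    return float(min(max(cai, 0.0), 100.0))


def cai_record(
    subject_id: str,
    motile_a: float,
    motile_b: float,
    readout_min: int = 15,
    threshold: float = CAI_THRESHOLD,
) -> CAIRecord:
    """Build a :class:`CAIRecord`, computing the index and the screening flag."""
    if readout_min not in _VALID_READOUTS:
        raise ValueError(f"readout_min must be one of {_VALID_READOUTS}")
    cai = compute_cai(motile_a, motile_b)
    return CAIRecord(
        subject_id=subject_id,
        motile_a=motile_a,
        motile_b=motile_b,
        readout_min=readout_min,
        cai=cai,
        flagged=cai <= threshold,
    )


def screen_cohort(records: list, threshold: float = CAI_THRESHOLD) -> ScreeningReport:
    """Flag every record with CAI <= ``threshold`` (inclusive).

    ``records`` may be any sequence of objects with ``subject_id`` and
    ``cai`` attributes (e.g. :class:`CAIRecord` or synthetic cohort records).
    """
    if not records:
        raise ValueError("empty cohort")
    flagged = tuple(r.subject_id for r in records if r.cai <= threshold)
    n = len(records)
    return ScreeningReport(
        threshold=threshold,
        n_total=n,
        n_flagged=len(flagged),
        fraction_flagged=100.0 * len(flagged) / n,
        flagged_ids=flagged,
    )


def estimate_prevalence(
    n_defective: int, n_group: int, male_factor_share: float = 0.5
) -> float:
    """Prevalence (%) of the defect among couples with a male-factor cause.

    ``100 * (n_defective / n_group) / male_factor_share`` — the observed
    frequency in the screened group scaled by the assumed share of couple
    infertility attributable to the man (default one half).
    """
    if n_group <= 0:
        raise ValueError("group size must be positive")
    if not 0 < male_factor_share <= 1:
        raise ValueError("male_factor_share must lie in (0, 1]")
    if n_defective > n_group or n_defective < 0:
        raise ValueError("n_defective must lie in [0, n_group]")
    return 100.0 * (n_defective / n_group) / male_factor_share
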