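"""Small assay metrics: fertilization rate, viscous-medium penetration.

Rates are reported at one-decimal precision with half-up rounding; raw
values are retained on the dataclasses for downstream JSON output.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

__all__ = [
    "AssayCounts",
    "PenetrationResult",
    "fertilization_rate",
    "penetration_normalize",
    "fold_change",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (the convention used for reported rates)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class AssayCounts:
    """A numerator/denominator pair, e.g. fertilized / injected oocytes."""

    label: str
    numerator: int
    denominator: int

    def __post_init__(self) -> None:
        if not 0 <= self.numerator <= self.denominator:
            raise ValueError("require 0 <= numerator <= denominator")


@dataclass(frozen=True)
class PenetrationResult:
    """Sperm count at the capillary mark, normalized to the motile fraction."""

    condition: str  # "vehicle" | "progesterone"
    count_at_mark: int
    motile_fraction: float  # %
    normalized_count: float


def fertilization_rate(counts: AssayCounts) -> float:
    """Percent fertilized, ``100 * numerator / denominator``, to one decimal."""
    if counts.denominator == 0:
        raise ValueError("zero denominator")
    return round_half_up(100.0 * counts.numerator / counts.denominator, 1)


def penetration_normalize(count_at_mark: int, motile_fraction: float) -> float:
    """Normalize a penetration count to the sample's motile fraction (%).

    Dividing by the motile fraction corrects for inter-sample variation in
    the number of sperm able to migrate at all.
    """
    if motile_fraction <= 0:
        raise ValueError("motile_fraction must be positive")
    if count_at_mark < 0:
        raise ValueError("count_at_mark cannot be negative")
    return count_at_mark / (motile_fraction / 100.0)


def fold_change(treated: float, reference: float) -> float:
    """Ratio of treated to reference (reference set to 1)."""
    if reference <= 0:
        raise ValueError("reference must be positive")
    return treated / reference
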