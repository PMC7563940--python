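"""Doubling arithmetic and the exponential tumour growth law.

A tumour is modelled as a sphere of identical 10 µm cells whose *volume*
doubles once every TVDT (tumour volume doubling time) days.  Volume scales
with the cube of the diameter, so one diameter doubling equals exactly
three volume doublings, and the number of volume doublings accumulated by
a sphere of diameter ``d`` grown from a single cell is

    N(d) = 3 * log2(d / cell_diameter)

with ``cell_diameter`` = 0.01 mm.  Every duration in the model is a
product ``doublings x TVDT``; the two-exam TVDT estimator is the Schwartz
formula ``TVDT = dt / (3 * log2(d2 / d1))``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date

__all__ = [
    "CompasError",
    "DomainError",
    "EstimationError",
    "OutOfModelError",
    "ModelConstants",
    "TumorMeasurement",
    "GrowthRate",
    "doublings_from_diameter",
    "diameter_from_doublings",
    "cell_count_from_doublings",
    "grow",
    "duration_days",
    "tvdt_from_measurements",
    "years",
]

TVDT_MIN_DAYS = 10.0
TVDT_MAX_DAYS = 310.0
#: TVDTs above this value lie beyond the slowest subtype band but are still
#: inside the model's stated validity range (flagged, not rejected).
TVDT_BAND_MAX_DAYS = 270.0


class CompasError(Exception):
    """Base class for model errors."""


class DomainError(CompasError, ValueError):
    """An input lies outside the model's mathematical domain."""


class EstimationError(CompasError, ValueError):
    """A growth rate cannot be estimated from the given measurements."""


class OutOfModelError(DomainError):
    """A quantity lies outside the model's stated validity range."""


@dataclass(frozen=True)
class ModelConstants:
    """Fixed kinetic anchors of the growth model.

    Attributes
    ----------
    cell_diameter : float
        Diameter of a single tumour cell, mm (10 µm).
    mts_detection_diameter : float
        Diameter at which a distant metastasis becomes clinically
        detectable, mm.
    pt_seeding_diameter : float
        Primary-tumour diameter at which metastatic seeding begins, mm.
        Its doubling count, ``3*log2(100) = 19.932``, anchors the
        pre-surgery (MTS-I) latency.
    seeding_doubling_index : float
        Integer doubling index of the primary tumour at which the first
        metastatic cell appears (the 20th doubling); anchors the
        post-surgery (MTS-II) latency.  The pair (19.932, 20) is kept
        deliberately: each anchors a different period of the published
        table and they are not interchangeable.
    lethal_doubling_count : float
        Doubling count of the lethal tumour burden (2**40 ~ 1.1e12 cells,
        ~102 mm sphere).
    whole_history_doublings : float
        Total doublings of the whole natural history; equals
        ``seeding_doubling_index + lethal_doubling_count``.
    days_per_year : float
        Calendar-year length used for all day/year conversions.
    linear_phase_theta : float
        Linear-phase coefficient carried for completeness; the pure
        exponential regime used throughout does not activate it.
    """

    cell_diameter: float = 0.01
    mts_detection_diameter: float = 9.0
    pt_seeding_diameter: float = 1.0
    seeding_doubling_index: float = 20.0
    lethal_doubling_count: float = 40.0
    whole_history_doublings: float = 60.0
    days_per_year: float = 365.25
    linear_phase_theta: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.cell_diameter < self.pt_seeding_diameter < self.mts_detection_diameter):
            raise DomainError(
                "diameters must satisfy 0 < cell < seeding < detection; got "
                f"{self.cell_diameter}, {self.pt_seeding_diameter}, "
                f"{self.mts_detection_diameter}"
            )
        if self.seeding_doubling_index + self.lethal_doubling_count != self.whole_history_doublings:
            raise DomainError(
                "seeding_doubling_index + lethal_doubling_count must equal "
                f"whole_history_doublings ({self.seeding_doubling_index} + "
                f"{self.lethal_doubling_count} != {self.whole_history_doublings})"
            )
        if self.days_per_year <= 0:
            raise DomainError("days_per_year must be positive")

    @property
    def seeding_diameter_doublings(self) -> float:
        """Doubling count of the PT at the seeding diameter (19.932 for 1 mm)."""
        return doublings_from_diameter(self.pt_seeding_diameter, self)

    @property
    def detection_doublings(self) -> float:
        """Doubling count of a metastasis at the detection diameter (29.441 for 9 mm)."""
        return doublings_from_diameter(self.mts_detection_diameter, self)


@dataclass(frozen=True)
class TumorMeasurement:
    """One dated diameter measurement of the primary tumour."""

    exam_date: date
    diameter_mm: float

    def __post_init__(self) -> None:
        if self.diameter_mm <= 0:
            raise DomainError(f"diameter must be positive, got {self.diameter_mm}")


@dataclass(frozen=True)
class GrowthRate:
    """A tumour volume doubling time in days.

    Valid TVDTs run from 10 to 310 days.  Values in (270, 310] are within
    the model but slower than the slowest subtype band; they carry the
    ``beyond_subtype_bands`` flag rather than raising.
    """

    tvdt_days: float

    def __post_init__(self) -> None:
        # snap float-epsilon boundary misses (e.g. a round-tripped 10 d
        # estimated back as 9.999999999999998) onto the bound
        for bound in (TVDT_MIN_DAYS, TVDT_MAX_DAYS):
            if self.tvdt_days != bound and abs(self.tvdt_days - bound) < 1e-9 * bound:
                object.__setattr__(self, "tvdt_days", bound)
        if not (TVDT_MIN_DAYS <= self.tvdt_days <= TVDT_MAX_DAYS):
            raise OutOfModelError(
                f"TVDT must lie in [{TVDT_MIN_DAYS:g}, {TVDT_MAX_DAYS:g}] days, "
                f"got {self.tvdt_days:g}"
            )

    @property
    def beyond_subtype_bands(self) -> bool:
        return self.tvdt_days > TVDT_BAND_MAX_DAYS


_DEFAULT = ModelConstants()


def doublings_from_diameter(d: float, c: ModelConstants = _DEFAULT) -> float:
    """Volume-doubling count of a sphere of diameter ``d`` mm grown from one cell.

    ``N = 3 * log2(d / cell_diameter)``.
    """
    if d < c.cell_diameter:
        raise DomainError(
            f"diameter {d} mm is below a single cell ({c.cell_diameter} mm)"
        )
    return 3.0 * math.log2(d / c.cell_diameter)


def diameter_from_doublings(n: float, c: ModelConstants = _DEFAULT) -> float:
    """Diameter in mm after ``n`` volume doublings from a single cell (inverse of
    :func:`doublings_from_diameter`)."""
    if n < 0:
        raise DomainError(f"doubling count must be non-negative, got {n}")
    return c.cell_diameter * 2.0 ** (n / 3.0)


def cell_count_from_doublings(n: float) -> float:
    """Number of cells after ``n`` volume doublings from a single cell (2**n)."""
    if n < 0:
        raise DomainError(f"doubling count must be non-negative, got {n}")
    return 2.0**n


def grow(d0: float, rate: GrowthRate, t_days: float) -> float:
    """Diameter after ``t_days`` of exponential growth from ``d0`` mm.

    The volume doubles every ``rate.tvdt_days``, so the diameter follows
    ``d0 * 2**(t / (3 * TVDT))``.
    """
    if d0 <= 0:
        raise DomainError(f"initial diameter must be positive, got {d0}")
    if t_days < 0:
        raise DomainError(f"time must be non-negative, got {t_days}")
    return d0 * 2.0 ** (t_days / (3.0 * rate.tvdt_days))


def duration_days(n: float, rate: GrowthRate) -> float:
    """Days needed for ``n`` volume doublings at the given rate (``n * TVDT``)."""
    if n < 0:
        raise DomainError(f"doubling count must be non-negative, got {n}")
    return n * rate.tvdt_days


def tvdt_from_measurements(m1: TumorMeasurement, m2: TumorMeasurement) -> GrowthRate:
    """Schwartz-type TVDT estimate from two dated diameter measurements.

    ``TVDT = dt / (3 * log2(d2 / d1))`` — the exact inverse of :func:`grow`.

    Raises
    ------
    EstimationError
        If the second exam is not later than the first or the tumour has
        not grown between the exams.
    OutOfModelError
        If the estimated TVDT falls outside [10, 310] days.
    """
    dt = (m2.exam_date - m1.exam_date).days
    if dt <= 0:
        raise EstimationError(
            "second exam must be later than the first "
            f"({m1.exam_date} -> {m2.exam_date})"
        )
    if m2.diameter_mm <= m1.diameter_mm:
        raise EstimationError(
            "no growth between exams "
            f"({m1.diameter_mm} mm -> {m2.diameter_mm} mm); TVDT is not estimable"
        )
    n = 3.0 * math.log2(m2.diameter_mm / m1.diameter_mm)
    return GrowthRate(dt / n)


def years(t_days: float, c: ModelConstants = _DEFAULT) -> float:
    """Convert a duration in days to years (``t / days_per_year``)."""
    if t_days < 0:
        raise DomainError(f"duration must be non-negative, got {t_days}")
    return t_days / c.days_per_year
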