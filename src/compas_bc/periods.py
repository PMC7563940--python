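"""Scenario calculators for the four metastasis growth periods.

For a primary tumour (PT) resected at diameter ``d_pt`` and a metastasis
growing at a fixed TVDT ``T``, the natural history splits into four
periods, each a doubling count times ``T``:

* non-visible MTS-I  — from the metastasis's first cell to PT resection;
* non-visible MTS-II — from resection to the 9 mm detection threshold
  (the metastasis-free interval);
* visible MTS        — from 9 mm to the lethal 40-doubling burden;
* survival           — MTS-II + visible.

Two bracketing scenarios are computed per TVDT band.  In the *earliest*
scenario the lesion is already 1 mm at surgery and grows at the band's
fastest TVDT; in the *latest* scenario the lesion was seeded as a single
cell at the PT's 20th doubling and grows at the band's slowest TVDT.  The
*seeded-at-surgery* window spreads the post-surgery latency between a
lesion seeded when the PT passed 1 mm and a single cell seeded at the
moment of resection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from .growth import (
    DomainError,
    GrowthRate,
    ModelConstants,
    doublings_from_diameter,
)
from .subtypes import SubtypeBand

__all__ = [
    "PeriodSet",
    "ScenarioInputs",
    "earliest_scenario",
    "latest_scenario",
    "earliest_periods",
    "latest_periods",
    "seeded_at_surgery_window",
    "seeding_spread_width_years",
    "whole_history_identity",
]

Scenario = Literal["earliest", "latest", "seeded_at_surgery"]


@dataclass(frozen=True)
class PeriodSet:
    """The four period durations (years) for one scenario at one TVDT."""

    mts1_years: float
    mts2_years: float
    visible_years: float
    survival_years: float
    tvdt_mts_days: float
    scenario: Scenario


@dataclass(frozen=True)
class ScenarioInputs:
    """PT diameter at surgery, its subtype band and the model constants."""

    d_pt_at_surgery: float
    band: SubtypeBand
    constants: ModelConstants = ModelConstants()

    def __post_init__(self) -> None:
        if self.d_pt_at_surgery <= self.constants.pt_seeding_diameter:
            raise DomainError(
                f"PT diameter {self.d_pt_at_surgery} mm has not passed the "
                f"metastasising threshold ({self.constants.pt_seeding_diameter} mm)"
            )


def _years(n_doublings: float, tvdt_days: float, c: ModelConstants) -> float:
    return n_doublings * tvdt_days / c.days_per_year


def earliest_periods(
    tvdt_days: float, c: ModelConstants = ModelConstants()
) -> PeriodSet:
    """Fast-extreme periods: the lesion is already at the seeding diameter
    (1 mm) when the PT is resected and grows at ``tvdt_days``."""
    GrowthRate(tvdt_days)  # validate range
    n1 = c.seeding_diameter_doublings
    n9 = c.detection_doublings
    mts1 = _years(n1, tvdt_days, c)
    mts2 = _years(n9 - n1, tvdt_days, c)
    visible = _years(c.lethal_doubling_count - n9, tvdt_days, c)
    return PeriodSet(mts1, mts2, visible, mts2 + visible, tvdt_days, "earliest")


def latest_periods(
    d_pt: float, tvdt_days: float, c: ModelConstants = ModelConstants()
) -> PeriodSet:
    """Slow-extreme periods: the lesion was seeded as a single cell at the
    PT's 20th doubling; by surgery it has accumulated ``N_pt - 20``
    doublings, all at ``tvdt_days``."""
    GrowthRate(tvdt_days)
    npt = doublings_from_diameter(d_pt, c)
    if npt <= c.seeding_doubling_index:
        raise DomainError(
            f"PT below seeding size: {d_pt} mm is only {npt:.2f} doublings "
            f"(seeding occurs at doubling {c.seeding_doubling_index:g})"
        )
    n9 = c.detection_doublings
    mts1 = _years(npt - c.seeding_diameter_doublings, tvdt_days, c)
    mts2 = _years(n9 - (npt - c.seeding_doubling_index), tvdt_days, c)
    visible = _years(c.lethal_doubling_count - n9, tvdt_days, c)
    return PeriodSet(mts1, mts2, visible, mts2 + visible, tvdt_days, "latest")


def earliest_scenario(inputs: ScenarioInputs) -> PeriodSet:
    """Earliest periods at the band's fastest TVDT (band minimum)."""
    return earliest_periods(inputs.band.tvdt_mts_range[0], inputs.constants)


def latest_scenario(inputs: ScenarioInputs) -> PeriodSet:
    """Latest periods at the band's slowest TVDT (band maximum)."""
    return latest_periods(
        inputs.d_pt_at_surgery, inputs.band.tvdt_mts_range[1], inputs.constants
    )


def seeded_at_surgery_window(
    d_pt: float, rate: GrowthRate | float, c: ModelConstants = ModelConstants()
) -> tuple[float, float]:
    """Spread of the post-surgery latency (MTS-II, years) at fixed TVDT.

    The low end is the latency of a lesion seeded when the PT passed the
    seeding diameter (``N_pt - 20`` doublings old at surgery); the high
    end is that of a single cell seeded at the moment of resection (the
    full ``N(9 mm)`` doublings still ahead).  The window's width is
    ``(N_pt - 19.932) * T`` — the "(+)" diagnosis-period extension.
    """
    tvdt = rate.tvdt_days if isinstance(rate, GrowthRate) else float(rate)
    low = latest_periods(d_pt, tvdt, c).mts2_years
    high = _years(c.detection_doublings, tvdt, c)
    return (low, high)


def seeding_spread_width_years(
    d_pt: float, rate: GrowthRate | float, c: ModelConstants = ModelConstants()
) -> float:
    """Width of the seeded-at-surgery window: ``(N_pt - 19.932) * T`` years."""
    tvdt = rate.tvdt_days if isinstance(rate, GrowthRate) else float(rate)
    GrowthRate(tvdt)
    npt = doublings_from_diameter(d_pt, c)
    if npt <= c.seeding_doubling_index:
        raise DomainError(f"PT below seeding size ({d_pt} mm)")
    return _years(npt - c.seeding_diameter_doublings, tvdt, c)


def whole_history_identity(d_pt: float, c: ModelConstants = ModelConstants()) -> float:
    """Total doublings of the whole natural history.

    ``N_pt + [N(9) - (N_pt - 20)] + [40 - N(9)]`` — the PT terms cancel
    algebraically, so the result is exactly ``20 + 40 = 60`` for every
    PT diameter.
    """
    npt = doublings_from_diameter(d_pt, c)
    n9 = c.detection_doublings
    mts2 = n9 - (npt - c.seeding_doubling_index)
    visible = c.lethal_doubling_count - n9
    return npt + mts2 + visible
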