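"""Personalised surveillance calendars from a diagnostic column.

Each chained detection window becomes one schedule entry: multimodal
examinations start at the window's opening, repeat at the band's
screening interval, and stay inside the window (the residual gap to the
window end is always shorter than one interval, and the next window's
first exam closes it).  The plan ends at the considered-healthy horizon
— the column's total diagnosis period after surgery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date, timedelta
from typing import Literal, Optional

from dateutil.relativedelta import relativedelta

from .growth import DomainError, ModelConstants
from .subtypes import BandRegistry
from .table import DiagnosticColumn

__all__ = ["ScheduleEntry", "SurveillancePlan", "build_plan", "exam_count", "to_icalendar"]

#: Mean synodic month length in days, used by exact-day stepping.
DAYS_PER_MONTH = 30.44


@dataclass(frozen=True)
class ScheduleEntry:
    """One surveillance window: band, bounds (years post-surgery), exams."""

    band_id: str
    window_start_years: float
    window_end_years: float
    interval_months: int
    exam_dates: Optional[tuple[date, ...]] = None

    @property
    def n_exams(self) -> int:
        if self.exam_dates is not None:
            return len(self.exam_dates)
        length_months = (self.window_end_years - self.window_start_years) * 12.0
        return int(math.floor(length_months / self.interval_months + 1e-9)) + 1


@dataclass(frozen=True)
class SurveillancePlan:
    """The full calendar plus the considered-healthy horizon."""

    surgery_date: Optional[date]
    entries: tuple[ScheduleEntry, ...]
    healthy_after_years: float
    healthy_date: Optional[date]


def _exam_dates(
    start: date, length_months: float, interval_months: int, month_stepping: bool
) -> tuple[date, ...]:
    n_steps = int(math.floor(length_months / interval_months + 1e-9))
    if month_stepping:
        return tuple(start + relativedelta(months=interval_months * k) for k in range(n_steps + 1))
    step = timedelta(days=interval_months * DAYS_PER_MONTH)
    return tuple(start + timedelta(days=round(interval_months * DAYS_PER_MONTH * k)) for k in range(n_steps + 1))


def build_plan(
    column: DiagnosticColumn,
    surgery_date: Optional[date] = None,
    interval_source: Literal["table", "narrative"] = "table",
    registry: Optional[BandRegistry] = None,
    month_stepping: bool = True,
) -> SurveillancePlan:
    """Turn a chained diagnostic column into a surveillance plan.

    Without a surgery date the plan is relative (years post-surgery,
    ``exam_dates`` unset).  With one, exam dates step by whole calendar
    months from each window's first exam (or by exact 30.44-day months
    when ``month_stepping`` is False).  The narrative interval source
    differs from the table source only for the slowest band (9 vs 12
    months).
    """
    registry = registry or BandRegistry.default()
    c = column.constants
    entries: list[ScheduleEntry] = []
    for w in column.windows:
        if w.chained_start is None or w.chained_end is None:
            raise DomainError("column must be chained before planning")
        interval = w.screening_interval_months
        if interval_source == "narrative":
            base_id = w.band_id.rstrip("+")
            if w.is_plus_row:
                slower = registry.slower_than(registry[base_id])
                src = slower if slower is not None else registry[base_id]
            else:
                src = registry[base_id]
            interval = src.screening_interval_narrative_months
        exam_dates = None
        if surgery_date is not None:
            start_date = surgery_date + timedelta(
                days=round(w.chained_start * c.days_per_year)
            )
            length_months = (w.chained_end - w.chained_start) * 12.0
            exam_dates = _exam_dates(start_date, length_months, interval, month_stepping)
        entries.append(
            ScheduleEntry(
                band_id=w.band_id,
                window_start_years=w.chained_start,
                window_end_years=w.chained_end,
                interval_months=interval,
                exam_dates=exam_dates,
            )
        )
    healthy_after = column.total_diagnosis_years
    healthy_date = None
    if surgery_date is not None:
        healthy_date = surgery_date + timedelta(days=round(healthy_after * c.days_per_year))
    return SurveillancePlan(
        surgery_date=surgery_date,
        entries=tuple(entries),
        healthy_after_years=healthy_after,
        healthy_date=healthy_date,
    )


def exam_count(plan: SurveillancePlan) -> int:
    """Total number of scheduled examinations."""
    return sum(e.n_exams for e in plan.entries)


def to_icalendar(plan: SurveillancePlan, summary: str = "Multimodal examination") -> str:
    """RFC 5545 iCalendar export: one all-day VEVENT per examination."""
    if plan.surgery_date is None:
        raise DomainError("an iCalendar export needs a surgery date")
    lines = [
        "BEGIN:VCALENDAR",
        "VERSION:2.0",
        "PRODID:-//compas-bc//surveillance//EN",
    ]
    for entry in plan.entries:
        for i, d in enumerate(entry.exam_dates or ()):
            stamp = d.strftime("%Y%m%d")
            lines += [
                "BEGIN:VEVENT",
                f"UID:{stamp}-{entry.band_id}-{i}@compas-bc",
                f"DTSTAMP:{plan.surgery_date.strftime('%Y%m%d')}T000000Z",
                f"DTSTART;VALUE=DATE:{stamp}",
                f"SUMMARY:{summary} (band {entry.band_id}, "
                f"every {entry.interval_months} mo)",
                "END:VEVENT",
            ]
    lines.append("END:VCALENDAR")
    return "\r\n".join(lines) + "\r\n"
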