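"""Two-exam prognosis contract, record I/O and the synthetic cohort generator.

The clinical contract mirrors the companion application: two dated
primary-tumour diameter measurements (plus optional receptor status) go
in; out comes the estimated TVDT, the kinetic subtype band, a prognosis
category, the number of months before the earliest possible metastasis
manifestation, the considered-healthy horizon and a full surveillance
plan.

Records travel as CSV (header ``patient_id,date1,d1_mm,date2,d2_mm,er,
pr,her2,ki67``) or JSON; malformed rows are collected with their line
numbers while valid rows are still processed.  The synthetic generator
draws patients whose diameters follow the exponential growth law between
two exam dates with multiplicative lognormal measurement noise, which
makes the whole pipeline testable end to end.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass
from datetime import date, timedelta
from pathlib import Path
from typing import Literal, Optional

import numpy as np

from .growth import (
    CompasError,
    DomainError,
    GrowthRate,
    ModelConstants,
    TumorMeasurement,
    grow,
    tvdt_from_measurements,
)
from .periods import earliest_periods
from .schedule import SurveillancePlan, build_plan
from .subtypes import BandRegistry, ReceptorStatus
from .table import build_column

__all__ = [
    "PatientRecord",
    "PrognosisReport",
    "RecordError",
    "run_prognosis",
    "read_records",
    "write_report",
    "report_to_dict",
    "synth_generate",
    "synth_cohort",
    "stage_t_from_diameter",
]

_T_CATEGORIES = (("T1a", 5.0), ("T1b", 10.0), ("T1c", 20.0), ("T2", 50.0))


def stage_t_from_diameter(d_mm: float) -> str:
    """TNM T category from the PT diameter (T1a <=5 < T1b <=10 < T1c <=20
    < T2 <=50 < T3)."""
    if d_mm <= 0:
        raise DomainError(f"diameter must be positive, got {d_mm}")
    for label, upper in _T_CATEGORIES:
        if d_mm <= upper:
            return label
    return "T3"


@dataclass(frozen=True)
class PatientRecord:
    """Two dated diameter measurements plus optional receptor status."""

    patient_id: str
    first_exam: TumorMeasurement
    second_exam: TumorMeasurement
    receptor_status: Optional[ReceptorStatus] = None
    stage_t: Optional[str] = None

    def __post_init__(self) -> None:
        if self.second_exam.exam_date <= self.first_exam.exam_date:
            raise DomainError(
                f"record {self.patient_id}: second exam must be after the first"
            )
        derived = stage_t_from_diameter(self.second_exam.diameter_mm)
        if self.stage_t is None:
            object.__setattr__(self, "stage_t", derived)
        elif self.stage_t != derived:
            raise DomainError(
                f"record {self.patient_id}: stage {self.stage_t} inconsistent with "
                f"diameter {self.second_exam.diameter_mm} mm ({derived})"
            )


@dataclass(frozen=True)
class RecordError:
    """A rejected input row: its line (or index) and the reason."""

    line: int
    reason: str


@dataclass(frozen=True)
class PrognosisReport:
    """Model output for one patient."""

    patient_id: str
    tvdt_pt_days: float
    subtype_band: str
    prognosis_category: str
    months_to_earliest_manifestation: float
    healthy_after_years: float
    plan: SurveillancePlan
    constants: ModelConstants
    warnings: tuple[str, ...] = ()


def run_prognosis(
    record: PatientRecord,
    registry: Optional[BandRegistry] = None,
    constants: Optional[ModelConstants] = None,
    interval_source: Literal["table", "narrative"] = "table",
    strict: bool = False,
) -> PrognosisReport:
    """Two exams in, prognosis out.

    The TVDT comes from the measured pair; the band from that TVDT (the
    measured kinetics drive the schedule).  When receptor status is also
    present it is classified independently as a cross-check; a mismatch is
    a warning, or an error in strict mode.  Categories: band I favorable,
    II-IV mid-favorable, V unfavorable.
    """
    registry = registry or BandRegistry.default()
    constants = constants or ModelConstants()
    rate = tvdt_from_measurements(record.first_exam, record.second_exam)
    notes: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        band = registry.band_for_tvdt(rate)
        notes.extend(str(w.message) for w in caught)
    if record.receptor_status is not None:
        receptor_band = registry.classify(record.receptor_status)
        if receptor_band.band_id != band.band_id:
            msg = (
                f"receptor status suggests band {receptor_band.band_id} but the "
                f"measured TVDT ({rate.tvdt_days:.1f} d) falls in band "
                f"{band.band_id}; using the measured kinetics"
            )
            if strict:
                raise DomainError(msg)
            notes.append(msg)
    column = build_column(
        band.band_id, record.second_exam.diameter_mm, registry, constants
    )
    plan = build_plan(
        column,
        surgery_date=record.second_exam.exam_date,
        interval_source=interval_source,
        registry=registry,
    )
    rapid_min = min(b.tvdt_mts_range[0] for b in registry)
    months_earliest = earliest_periods(rapid_min, constants).mts2_years * 12.0
    return PrognosisReport(
        patient_id=record.patient_id,
        tvdt_pt_days=rate.tvdt_days,
        subtype_band=band.band_id,
        prognosis_category=band.prognosis_app_label,
        months_to_earliest_manifestation=months_earliest,
        healthy_after_years=column.total_diagnosis_years,
        plan=plan,
        constants=constants,
        warnings=tuple(notes),
    )


# ---------------------------------------------------------------- I/O


_CSV_HEADER = ["patient_id", "date1", "d1_mm", "date2", "d2_mm", "er", "pr", "her2", "ki67"]


def _parse_tristate(token: str) -> Optional[bool]:
    token = token.strip()
    if token in {"", "?", "unknown", "NA", "na"}:
        return None
    if token in {"+", "pos", "positive", "1", "true", "True"}:
        return True
    if token in {"-", "neg", "negative", "0", "false", "False"}:
        return False
    raise ValueError(f"cannot parse receptor value {token!r}")


def _receptors_from_tokens(
    er: str, pr: str, her2: str, ki67: str
) -> Optional[ReceptorStatus]:
    if not any(t.strip() for t in (er, pr, her2, ki67)):
        return None
    her2_val = _parse_tristate(her2)
    if her2_val is None:
        raise ValueError("HER2 status must be + or -")
    return ReceptorStatus(
        er=_parse_tristate(er),
        pr=_parse_tristate(pr),
        her2=her2_val,
        ki67_percent=float(ki67) if ki67.strip() else 0.0,
    )


def _check_growing(rec: PatientRecord) -> PatientRecord:
    if rec.second_exam.diameter_mm <= rec.first_exam.diameter_mm:
        raise ValueError(
            f"record {rec.patient_id}: diameter did not grow between exams "
            f"({rec.first_exam.diameter_mm} -> {rec.second_exam.diameter_mm} mm)"
        )
    return rec


def _record_from_row(row: dict[str, str]) -> PatientRecord:
    return PatientRecord(
        patient_id=row["patient_id"].strip(),
        first_exam=TumorMeasurement(
            date.fromisoformat(row["date1"].strip()), float(row["d1_mm"])
        ),
        second_exam=TumorMeasurement(
            date.fromisoformat(row["date2"].strip()), float(row["d2_mm"])
        ),
        receptor_status=_receptors_from_tokens(
            row.get("er", ""), row.get("pr", ""), row.get("her2", ""), row.get("ki67", "")
        ),
    )


def read_records(
    path: str | Path, format: Optional[Literal["csv", "json"]] = None
) -> tuple[list[PatientRecord], list[RecordError]]:
    """Read patient records; invalid rows are collected, valid ones kept."""
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    records: list[PatientRecord] = []
    errors: list[RecordError] = []
    if fmt == "csv":
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            for i, row in enumerate(reader, start=2):  # line 1 is the header
                try:
                    records.append(_check_growing(_record_from_row(row)))
                except (CompasError, ValueError, KeyError, TypeError) as exc:
                    errors.append(RecordError(line=i, reason=str(exc)))
    elif fmt == "json":
        with open(path, encoding="utf-8") as fh:
            data = json.load(fh)
        for i, obj in enumerate(data):
            try:
                rec = obj.get("receptors") or {}
                records.append(
                    _check_growing(PatientRecord(
                        patient_id=str(obj["patient_id"]),
                        first_exam=TumorMeasurement(
                            date.fromisoformat(obj["first_exam"]["date"]),
                            float(obj["first_exam"]["diameter_mm"]),
                        ),
                        second_exam=TumorMeasurement(
                            date.fromisoformat(obj["second_exam"]["date"]),
                            float(obj["second_exam"]["diameter_mm"]),
                        ),
                        receptor_status=(
                            ReceptorStatus(
                                er=rec.get("er"),
                                pr=rec.get("pr"),
                                her2=bool(rec["her2"]),
                                ki67_percent=float(rec.get("ki67_percent", 0.0)),
                            )
                            if rec
                            else None
                        ),
                    ))
                )
            except (CompasError, ValueError, KeyError, TypeError) as exc:
                errors.append(RecordError(line=i, reason=str(exc)))
    else:
        raise DomainError(f"unknown record format {format!r}")
    return records, errors


def _tristate_token(v: Optional[bool]) -> str:
    return "" if v is None else ("+" if v else "-")


def write_records(records: list[PatientRecord], path: str | Path) -> None:
    """Write records as CSV (lossless round-trip with :func:`read_records`)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_HEADER)
        for r in records:
            rs = r.receptor_status
            writer.writerow(
                [
                    r.patient_id,
                    r.first_exam.exam_date.isoformat(),
                    repr(r.first_exam.diameter_mm),
                    r.second_exam.exam_date.isoformat(),
                    repr(r.second_exam.diameter_mm),
                    _tristate_token(rs.er) if rs else "",
                    _tristate_token(rs.pr) if rs else "",
                    _tristate_token(rs.her2) if rs else "",
                    repr(rs.ki67_percent) if rs else "",
                ]
            )


def report_to_dict(report: PrognosisReport) -> dict:
    """JSON-ready view of a report (constants embedded for auditability)."""
    c = report.constants
    plan = report.plan
    return {
        "patient_id": report.patient_id,
        "tvdt_pt_days": report.tvdt_pt_days,
        "subtype_band": report.subtype_band,
        "prognosis_category": report.prognosis_category,
        "months_to_earliest_manifestation": report.months_to_earliest_manifestation,
        "healthy_after_years": report.healthy_after_years,
        "healthy_date": plan.healthy_date.isoformat() if plan.healthy_date else None,
        "plan": [
            {
                "band_id": e.band_id,
                "window_start_years": e.window_start_years,
                "window_end_years": e.window_end_years,
                "interval_months": e.interval_months,
                "exam_dates": [d.isoformat() for d in (e.exam_dates or ())],
            }
            for e in plan.entries
        ],
        "warnings": list(report.warnings),
        "constants": {
            "cell_diameter_mm": c.cell_diameter,
            "mts_detection_diameter_mm": c.mts_detection_diameter,
            "pt_seeding_diameter_mm": c.pt_seeding_diameter,
            "seeding_doubling_index": c.seeding_doubling_index,
            "lethal_doubling_count": c.lethal_doubling_count,
            "whole_history_doublings": c.whole_history_doublings,
            "days_per_year": c.days_per_year,
        },
    }


def write_report(
    report: PrognosisReport, path: str | Path, format: Literal["json"] = "json"
) -> None:
    """Serialise a report to JSON (deterministic: sorted keys, no timestamps)."""
    if format != "json":
        raise DomainError(f"unknown report format {format!r}")
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report_to_dict(report), fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------- synthetic cohorts


def _receptors_for_band(band_id: str, rng: np.random.Generator) -> ReceptorStatus:
    ki_low = float(rng.uniform(1.0, 13.0))
    ki_high = float(rng.uniform(14.0, 80.0))
    pr = bool(rng.integers(0, 2))
    if band_id == "I":
        return ReceptorStatus(er=True, pr=pr, her2=False, ki67_percent=ki_low)
    if band_id == "II":
        return ReceptorStatus(er=True, pr=pr, her2=True, ki67_percent=ki_high)
    if band_id == "III":
        return ReceptorStatus(er=True, pr=pr, her2=False, ki67_percent=ki_high)
    if band_id == "IV":
        return ReceptorStatus(er=False, pr=False, her2=True, ki67_percent=ki_high)
    return ReceptorStatus(er=False, pr=False, her2=False, ki67_percent=ki_high)


def synth_cohort(
    n: int,
    seed: int,
    registry: Optional[BandRegistry] = None,
    constants: Optional[ModelConstants] = None,
    sigma: float = 0.05,
    base_date: date = date(2024, 1, 1),
) -> tuple[list[PatientRecord], list[dict]]:
    """Generate ``n`` synthetic records plus their ground truth.

    Per record: a band drawn uniformly, a TVDT uniform within the band's
    PT range, a first diameter uniform in [5, 15] mm, an inter-exam gap
    uniform in [60, 365] days; the second diameter is the exponential
    growth result times multiplicative lognormal noise of scale ``sigma``.
    Receptor status is drawn consistent with the band.  Fully reproducible
    under a fixed seed.
    """
    if n < 1:
        raise DomainError(f"cohort size must be >= 1, got {n}")
    registry = registry or BandRegistry.default()
    constants = constants or ModelConstants()
    rng = np.random.default_rng(seed)
    bands = list(registry)
    records: list[PatientRecord] = []
    truth: list[dict] = []
    for i in range(n):
        band = bands[int(rng.integers(0, len(bands)))]
        lo, hi = band.tvdt_pt_range
        tvdt = float(rng.uniform(lo, hi))
        d1 = float(rng.uniform(5.0, 15.0))
        gap = int(rng.integers(60, 366))
        offset = int(rng.integers(0, 366))
        noise = float(rng.lognormal(mean=0.0, sigma=sigma)) if sigma > 0 else 1.0
        d2 = grow(d1, GrowthRate(tvdt), gap) * noise
        first = base_date + timedelta(days=offset)
        rec = PatientRecord(
            patient_id=f"SYN-{i:04d}",
            first_exam=TumorMeasurement(first, d1),
            second_exam=TumorMeasurement(first + timedelta(days=gap), d2),
            receptor_status=_receptors_for_band(band.band_id, rng),
        )
        records.append(rec)
        truth.append({"patient_id": rec.patient_id, "band_id": band.band_id, "tvdt_days": tvdt})
    return records, truth


def synth_generate(
    n: int,
    seed: int,
    registry: Optional[BandRegistry] = None,
    constants: Optional[ModelConstants] = None,
    sigma: float = 0.05,
) -> list[PatientRecord]:
    """Synthetic records only (see :func:`synth_cohort` for the truth too)."""
    return synth_cohort(n, seed, registry, constants, sigma)[0]
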