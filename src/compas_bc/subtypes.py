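"""The five ER/PR/HER2/Ki-67 subtype groups and their TVDT bands.

Breast-cancer primary tumours fall into five kinetic groups by receptor
status and proliferation marker.  Each group carries a closed integer-day
TVDT band (the five metastasis bands partition [10, 270] days), a
prognosis label, and a recommended multimodal-screening interval.
Classification works either from receptor status (``classify``) or from a
measured TVDT (``band_for_tvdt``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Literal, Optional

import yaml

from .growth import DomainError, GrowthRate, TVDT_BAND_MAX_DAYS, TVDT_MIN_DAYS

__all__ = ["ReceptorStatus", "SubtypeBand", "BandRegistry", "KI67_CUTOFF_PERCENT"]

#: Ki-67 labelling-index threshold separating luminal A from luminal B.
KI67_CUTOFF_PERCENT = 14.0

IntervalSource = Literal["table", "narrative"]


@dataclass(frozen=True)
class ReceptorStatus:
    """ER/PR/HER2/Ki-67 immunophenotype of a primary tumour.

    ``er`` and ``pr`` are tri-state (True/False/None for unknown); ``her2``
    is binary; ``ki67_percent`` is the labelling index in percent.
    """

    er: Optional[bool]
    pr: Optional[bool]
    her2: bool
    ki67_percent: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.ki67_percent <= 100.0):
            raise DomainError(
                f"Ki-67 must lie in [0, 100] percent, got {self.ki67_percent}"
            )

    @property
    def hr_positive(self) -> bool:
        """Hormone-receptor positivity: ER+ or PR+."""
        return bool(self.er) or bool(self.pr)


@dataclass(frozen=True)
class SubtypeBand:
    """One subtype group: receptor rule, TVDT bands, prognosis, screening."""

    band_id: str
    label: str
    receptor_rule: str
    tvdt_pt_range: tuple[int, int]
    tvdt_pt_display: tuple[int, int]
    tvdt_mts_range: tuple[int, int]
    mean_tvdt_mts_range: tuple[int, int]
    growth_class: str
    prognosis_table_label: str
    prognosis_app_label: str
    screening_interval_months: int
    screening_interval_narrative_months: int

    def contains_tvdt(self, tvdt_days: float) -> bool:
        """Band membership of a TVDT rounded to the nearest integer day."""
        lo, hi = self.tvdt_mts_range
        return lo <= round(tvdt_days) <= hi


class BandRegistry:
    """The ordered set of subtype bands, fastest (V) to slowest (I).

    The default registry ships as a YAML file inside the package and can
    be overridden per run with :meth:`from_yaml`.
    """

    def __init__(self, bands: list[SubtypeBand]):
        if not bands:
            raise DomainError("registry needs at least one band")
        self.bands = list(bands)
        self._by_id = {b.band_id: b for b in self.bands}
        if len(self._by_id) != len(self.bands):
            raise DomainError("duplicate band ids in registry")

    def __iter__(self):
        return iter(self.bands)

    def __getitem__(self, band_id: str) -> SubtypeBand:
        return self._by_id[band_id]

    # -- construction -------------------------------------------------

    @classmethod
    def from_mapping(cls, data: dict) -> "BandRegistry":
        bands = [
            SubtypeBand(
                band_id=str(b["band_id"]),
                label=str(b["label"]),
                receptor_rule=str(b["receptor_rule"]),
                tvdt_pt_range=tuple(b["tvdt_pt_range"]),
                tvdt_pt_display=tuple(b["tvdt_pt_display"]),
                tvdt_mts_range=tuple(b["tvdt_mts_range"]),
                mean_tvdt_mts_range=tuple(b["mean_tvdt_mts_range"]),
                growth_class=str(b["growth_class"]),
                prognosis_table_label=str(b["prognosis_table_label"]),
                prognosis_app_label=str(b["prognosis_app_label"]),
                screening_interval_months=int(b["screening_interval_months"]),
                screening_interval_narrative_months=int(
                    b["screening_interval_narrative_months"]
                ),
            )
            for b in data["bands"]
        ]
        return cls(bands)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "BandRegistry":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_mapping(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "BandRegistry":
        text = resources.files("compas_bc").joinpath("data/bands.yaml").read_text("utf-8")
        return cls.from_mapping(yaml.safe_load(text))

    # -- classification -----------------------------------------------

    def classify(self, status: ReceptorStatus) -> SubtypeBand:
        """Subtype band from receptor status.

        HR+/HER2-/Ki-67<14 -> I (luminal A); HR+/HER2+ -> II;
        HR+/HER2-/Ki-67>=14 -> III; HR-/HER2+ -> IV; HR-/HER2- -> V.
        Triple-negative with Ki-67 < 14 is still assigned to V, with a
        warning (the group definitions list only Ki-67 >= 14 there).
        """
        if status.er is None and status.pr is None:
            raise DomainError("at least one of ER/PR must be known to classify")
        if status.hr_positive:
            if status.her2:
                return self["II"]
            if status.ki67_percent < KI67_CUTOFF_PERCENT:
                return self["I"]
            return self["III"]
        if status.her2:
            return self["IV"]
        if status.ki67_percent < KI67_CUTOFF_PERCENT:
            warnings.warn(
                "triple-negative with Ki-67 < 14% has no dedicated group; "
                "assigned to band V",
                stacklevel=2,
            )
        return self["V"]

    def band_for_tvdt(self, rate: GrowthRate | float) -> SubtypeBand:
        """Band whose TVDT range contains the value.

        Real-valued TVDTs are rounded to the nearest integer day before
        lookup, matching the printed integer band edges.  TVDTs in
        (270, 310] days are slower than every band and map to band I with
        a warning.
        """
        tvdt = rate.tvdt_days if isinstance(rate, GrowthRate) else float(rate)
        if tvdt < TVDT_MIN_DAYS:
            raise DomainError(f"TVDT {tvdt:g} d is below the model minimum (10 d)")
        if tvdt > TVDT_BAND_MAX_DAYS:
            warnings.warn(
                f"TVDT {tvdt:g} d is beyond the slowest subtype band "
                "(270 d); assigned to band I",
                stacklevel=2,
            )
            return self._slowest()
        for band in self.bands:
            if band.contains_tvdt(tvdt):
                return band
        # rounding to integer days leaves no gaps in [10, 270]
        raise DomainError(f"no band contains TVDT {tvdt:g} d")  # pragma: no cover

    def screening_interval(
        self, band: SubtypeBand | str, source: IntervalSource = "table"
    ) -> int:
        """Screening interval in months, from the table or the prose source."""
        b = band if isinstance(band, SubtypeBand) else self[band]
        if source == "table":
            return b.screening_interval_months
        if source == "narrative":
            return b.screening_interval_narrative_months
        raise DomainError(f"unknown interval source {source!r}")

    def _slowest(self) -> SubtypeBand:
        return max(self.bands, key=lambda b: b.tvdt_mts_range[1])

    def slower_than(self, band: SubtypeBand) -> Optional[SubtypeBand]:
        """The next slower band, or None if ``band`` is the slowest."""
        slower = [b for b in self.bands if b.tvdt_mts_range[0] > band.tvdt_mts_range[1]]
        if not slower:
            return None
        return min(slower, key=lambda b: b.tvdt_mts_range[0])
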