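"""Food-composition groups and the commodity → group mapping.

Each FBS commodity is assigned to a composition group (pelagic fish,
demersal fish, eggs, ...) carrying an average vitamin D3 content and,
separately, a 25-hydroxyvitamin D3 (25(OH)D3) content, both in
μg/100 g edible portion. UK-style total vitamin D values count 25(OH)D3
at five times the potency of D3 ("bioactivity factor"); US-style values
exclude it. Both conventions are supported through
:class:`BioactivityOptions`.

The composition table shipped with the package is illustrative — it has
the right orders of magnitude (fatty fish ≫ eggs/meat > dairy > plant
staples ≈ 0) but is not a transcription of any national composition
database; users supply their own table via the documented CSV schema for
real analyses.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd

from .errors import ConfigurationError, FormatError, ValidationError

logger = logging.getLogger(__name__)

#: Sentinel group for commodities with no composition match; they
#: contribute zero vitamin D but are tracked in coverage reports.
UNMAPPED = None


@dataclass(frozen=True)
class CompositionEntry:
    """Average vitamin D content of one commodity group, μg/100 g."""

    group_id: str
    group_name: str
    vitd3_per_100g: float
    ohd3_per_100g: float = 0.0
    source: str = ""

    def __post_init__(self) -> None:
        if self.vitd3_per_100g < 0 or self.ohd3_per_100g < 0:
            raise ValidationError(
                f"negative composition value for group {self.group_id!r}")


@dataclass(frozen=True)
class BioactivityOptions:
    """How 25(OH)D3 enters the total vitamin D content.

    ``include_ohd=True`` adds ``bioactivity_factor × ohd3`` to the D3
    content (UK convention, factor 5 by default); ``False`` uses D3
    alone (US convention).
    """

    include_ohd: bool = True
    bioactivity_factor: float = 5.0

    def __post_init__(self) -> None:
        if self.bioactivity_factor <= 0:
            raise ValidationError("bioactivity_factor must be > 0")


def total_content(entry: CompositionEntry,
                  opts: BioactivityOptions = BioactivityOptions()) -> float:
    """Total vitamin D content of a group in μg/100 g under ``opts``."""
    if opts.include_ohd:
        return entry.vitd3_per_100g + opts.bioactivity_factor * entry.ohd3_per_100g
    return entry.vitd3_per_100g


@dataclass
class CompositionTable:
    """Lookup of group_id → :class:`CompositionEntry` (unique group ids)."""

    entries: dict = field(default_factory=dict)

    @classmethod
    def from_entries(cls, entries) -> "CompositionTable":
        table = cls()
        for e in entries:
            if e.group_id in table.entries:
                raise ConfigurationError(f"duplicate group_id {e.group_id!r}")
            table.entries[e.group_id] = e
        return table

    @classmethod
    def from_csv(cls, path) -> "CompositionTable":
        """Schema: group_id, group_name, vitd3_ug_per_100g, ohd3_ug_per_100g, source."""
        df = pd.read_csv(path)
        required = {"group_id", "group_name", "vitd3_ug_per_100g",
                    "ohd3_ug_per_100g"}
        missing = required - set(df.columns)
        if missing:
            raise FormatError(
                f"{Path(path).name}: missing column(s) {sorted(missing)}")
        return cls.from_entries(
            CompositionEntry(
                group_id=str(r.group_id), group_name=str(r.group_name),
                vitd3_per_100g=float(r.vitd3_ug_per_100g),
                ohd3_per_100g=float(r.ohd3_ug_per_100g),
                source=str(getattr(r, "source", "")),
            ) for r in df.itertuples())

    def __getitem__(self, group_id: str) -> CompositionEntry:
        return self.entries[group_id]

    def __contains__(self, group_id) -> bool:
        return group_id in self.entries

    def group_ids(self):
        return list(self.entries)


class CommodityMap:
    """Many-to-one commodity_code → group_id mapping.

    A commodity may be explicitly unmapped (group blank/NA in the CSV);
    unmapped commodities contribute zero vitamin D downstream and are
    surfaced through :func:`coverage`.
    """

    def __init__(self, mapping: Mapping):
        self._map = dict(mapping)
        self._warned: set = set()

    @classmethod
    def from_csv(cls, path) -> "CommodityMap":
        """Schema: commodity_code, commodity_name (optional), group_id."""
        df = pd.read_csv(path)
        required = {"commodity_code", "group_id"}
        missing = required - set(df.columns)
        if missing:
            raise FormatError(
                f"{Path(path).name}: missing column(s) {sorted(missing)}")
        mapping: dict = {}
        for r in df.itertuples():
            code = r.commodity_code
            group = None if pd.isna(r.group_id) else str(r.group_id)
            if code in mapping and mapping[code] != group:
                raise ConfigurationError(
                    f"commodity {code!r} mapped to both "
                    f"{mapping[code]!r} and {group!r}")
            mapping[code] = group
        return cls(mapping)

    def resolve(self, commodity_code) -> Optional[str]:
        """Group for a commodity, or :data:`UNMAPPED`; unknowns logged once."""
        group = self._map.get(commodity_code, UNMAPPED)
        if group is UNMAPPED and commodity_code not in self._warned:
            logger.info("commodity %r has no composition group; "
                        "treated as zero vitamin D", commodity_code)
            self._warned.add(commodity_code)
        return group

    def __contains__(self, code) -> bool:
        return code in self._map and self._map[code] is not UNMAPPED

    def codes_for_group(self, group_id: str) -> list:
        return [c for c, g in self._map.items() if g == group_id]


def resolve_group(commodity_code, mapping: CommodityMap) -> Optional[str]:
    """Functional wrapper around :meth:`CommodityMap.resolve`."""
    return mapping.resolve(commodity_code)


@dataclass(frozen=True)
class CoverageReport:
    """Mass accounting of how much supply the mapping covers."""

    mapped_g_day: float
    unmapped_g_day: float
    unmapped_codes: tuple

    @property
    def total_g_day(self) -> float:
        return self.mapped_g_day + self.unmapped_g_day

    @property
    def mapped_fraction(self) -> float:
        return 1.0 if self.total_g_day == 0 else self.mapped_g_day / self.total_g_day


def coverage(records: pd.DataFrame, mapping: CommodityMap) -> CoverageReport:
    """Mapped vs unmapped g/day totals for a records frame.

    The identity mapped + unmapped == total holds exactly: every record
    lands in exactly one of the two bins.
    """
    is_mapped = records["commodity_code"].map(lambda c: c in mapping)
    mapped = float(records.loc[is_mapped, "g_per_day"].sum())
    unmapped = float(records.loc[~is_mapped, "g_per_day"].sum())
    codes = tuple(sorted(set(records.loc[~is_mapped, "commodity_code"]),
                         key=str))
    report = CoverageReport(mapped, unmapped, codes)
    logger.info("mapping coverage: %.1f%% of supply mass (%d unmapped codes)",
                100 * report.mapped_fraction, len(codes))
    return report
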