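"""Domain types, validation and delimited-text I/O for stomach-content surveys.

The sampling design modelled here is a gillnet survey checked every three
hours over the 24-h cycle (eight checks: 18:00, 21:00, 24:00, 03:00, 06:00,
09:00, 12:00, 15:00) in an Amazonian reservoir with two hydrological
seasons: flood (January-June) and dry (July-December).  Each check label
denotes the END of its 3-h window, so the 18:00 and 06:00 checks both fall
in the nocturnal 18:00-06:00 period, giving a 5 nocturnal / 3 diurnal split
of sampling effort.
"""

from __future__ import annotations

import csv
import datetime as dt
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Iterator, Sequence

__all__ = [
    "INTERVALS",
    "NOCTURNAL_INTERVALS",
    "DIURNAL_INTERVALS",
    "CATEGORIES",
    "SEASONS",
    "SEXES",
    "REPLETION_CLASSES",
    "SchemaError",
    "RecordError",
    "EmptyGroupError",
    "SpecimenRecord",
    "StomachItem",
    "GroupKey",
    "season_of",
    "is_nocturnal",
    "read_specimens",
    "read_stomach_items",
    "write_specimens",
    "write_stomach_items",
    "select_specimens",
    "group_keys",
]

#: Net-check labels in chronological order from the 15:00 set time.
#: "24:00" is kept verbatim (not normalised to "00:00") — it is the
#: conventional label for the midnight check in this literature.
INTERVALS: tuple[str, ...] = (
    "18:00", "21:00", "24:00", "03:00", "06:00", "09:00", "12:00", "15:00",
)

#: Checks whose 3-h window lies in the nocturnal period 18:00-06:00.
NOCTURNAL_INTERVALS: frozenset[str] = frozenset(
    {"18:00", "21:00", "24:00", "03:00", "06:00"}
)
DIURNAL_INTERVALS: frozenset[str] = frozenset({"09:00", "12:00", "15:00"})

#: Broad food-item categories used for stomach-content standardisation.
CATEGORIES: tuple[str, ...] = (
    "fish", "crustacean", "microcrustacean", "insect", "plant", "other",
)

SEASONS: tuple[str, ...] = ("flood", "dry")
SEXES: tuple[str, ...] = ("male", "female", "undetermined")
#: Stomach repletion: void (empty), partly_full (25-75%), full (>75%).
REPLETION_CLASSES: tuple[str, ...] = ("void", "partly_full", "full")

SPECIMEN_COLUMNS = (
    "specimen_id", "species", "sex", "total_length_mm", "total_weight_g",
    "gutted_weight_g", "stomach_weight_g", "capture_date", "interval",
    "repletion",
)
ITEM_COLUMNS = ("specimen_id", "category", "volume")


class SchemaError(ValueError):
    """A file or mapping is missing columns or uses unknown labels."""


class RecordError(ValueError):
    """A single record violates a domain invariant."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"row {row}: {message}"
        super().__init__(message)


class EmptyGroupError(ValueError):
    """A grouped computation received no usable records."""


def season_of(date: dt.date) -> str:
    """Hydrological season of a calendar date.

    January-June is the rainy/flood season, July-December the dry season
    (month-granular, half-open boundaries).
    """
    return "flood" if date.month <= 6 else "dry"


def is_nocturnal(interval: str) -> bool:
    """Whether a net-check label falls in the nocturnal 18:00-06:00 period.

    A check at time *t* reports the catch of the preceding 3-h window, so
    the 06:00 check (window 03:00-06:00) is nocturnal and the 18:00 check
    (window 15:00-18:00) counts with the nightly sequence it opens.
    """
    if interval in NOCTURNAL_INTERVALS:
        return True
    if interval in DIURNAL_INTERVALS:
        return False
    raise SchemaError(
        f"unknown interval {interval!r}; expected one of {', '.join(INTERVALS)}"
    )


@dataclass(frozen=True)
class SpecimenRecord:
    """One captured fish with its morphometrics and capture context."""

    specimen_id: str
    species: str
    sex: str
    total_length: float  # mm
    total_weight: float  # g
    gutted_weight: float  # g
    stomach_weight: float  # g
    capture_date: dt.date
    interval: str
    repletion: str
    season: str = ""  # derived from capture_date when omitted

    def __post_init__(self) -> None:
        if not self.specimen_id:
            raise RecordError("specimen_id must be non-empty")
        if not self.species:
            raise RecordError("species must be non-empty")
        if self.sex not in SEXES:
            raise RecordError(
                f"sex {self.sex!r} not one of {', '.join(SEXES)}"
            )
        if not self.total_length > 0:
            raise RecordError(f"total_length must be > 0, got {self.total_length}")
        if not self.total_weight > 0:
            raise RecordError(f"total_weight must be > 0, got {self.total_weight}")
        if self.gutted_weight < 0 or self.stomach_weight < 0:
            raise RecordError("gutted_weight and stomach_weight must be >= 0")
        if self.gutted_weight > self.total_weight:
            raise RecordError(
                f"gutted_weight {self.gutted_weight} exceeds total_weight "
                f"{self.total_weight}"
            )
        if self.stomach_weight > self.total_weight:
            raise RecordError(
                f"stomach_weight {self.stomach_weight} exceeds total_weight "
                f"{self.total_weight}"
            )
        if self.interval not in INTERVALS:
            raise RecordError(
                f"interval {self.interval!r} not one of {', '.join(INTERVALS)}"
            )
        if self.repletion not in REPLETION_CLASSES:
            raise RecordError(
                f"repletion {self.repletion!r} not one of "
                f"{', '.join(REPLETION_CLASSES)}"
            )
        derived = season_of(self.capture_date)
        if self.season == "":
            object.__setattr__(self, "season", derived)
        elif self.season != derived:
            raise RecordError(
                f"season {self.season!r} disagrees with capture_date "
                f"{self.capture_date.isoformat()} ({derived})"
            )

    @property
    def nocturnal(self) -> bool:
        return is_nocturnal(self.interval)


@dataclass(frozen=True)
class StomachItem:
    """One (specimen, food category, volume) stomach-content observation."""

    specimen_id: str
    category: str
    volume: float

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise RecordError(
                f"category {self.category!r} not one of {', '.join(CATEGORIES)}"
            )
        if self.volume < 0:
            raise RecordError(f"volume must be >= 0, got {self.volume}")


@dataclass(frozen=True)
class GroupKey:
    """Selector for a (species, season, interval) cell; "all" collapses an axis."""

    species: str
    season: str = "all"
    interval: str = "all"

    def __post_init__(self) -> None:
        if self.season not in SEASONS and self.season != "all":
            raise SchemaError(f"season {self.season!r} not flood/dry/all")
        if self.interval not in INTERVALS and self.interval != "all":
            raise SchemaError(f"interval {self.interval!r} unknown")

    def matches(self, rec: SpecimenRecord) -> bool:
        if self.species != "all" and rec.species != self.species:
            return False
        if self.season != "all" and rec.season != self.season:
            return False
        if self.interval != "all" and rec.interval != self.interval:
            return False
        return True


def select_specimens(
    specimens: Iterable[SpecimenRecord], group: GroupKey
) -> list[SpecimenRecord]:
    """Specimens matching a group key, order preserved."""
    return [s for s in specimens if group.matches(s)]


def group_keys(
    specimens: Iterable[SpecimenRecord],
    by: Sequence[str] = ("species", "season"),
) -> list[GroupKey]:
    """Distinct group keys present in the data along the requested axes.

    ``by`` may contain "species", "season" and/or "interval"; omitted axes
    are collapsed with the "all" wildcard.
    """
    allowed = {"species", "season", "interval"}
    bad = set(by) - allowed
    if bad:
        raise SchemaError(f"unknown grouping axes: {sorted(bad)}")
    seen: dict[GroupKey, None] = {}
    for s in specimens:
        key = GroupKey(
            species=s.species if "species" in by else "all",
            season=s.season if "season" in by else "all",
            interval=s.interval if "interval" in by else "all",
        )
        seen.setdefault(key, None)
    return list(seen)


# ---------------------------------------------------------------------------
# Delimited-text I/O


def _sniff_delimiter(sample: str) -> str:
    """Pick the delimiter among comma/semicolon/tab with the most hits."""
    header = sample.splitlines()[0] if sample else ""
    counts = {d: header.count(d) for d in (",", ";", "\t")}
    best = max(counts, key=counts.get)  # type: ignore[arg-type]
    return best if counts[best] > 0 else ","


def _parse_float(text: str, decimal_comma: bool) -> float:
    if decimal_comma:
        text = text.replace(",", ".")
    return float(text)


def _open_rows(path: str | Path, delimiter: str | None):
    text = Path(path).read_text(encoding="utf-8")
    if delimiter is None:
        delimiter = _sniff_delimiter(text)
    reader = csv.DictReader(text.splitlines(), delimiter=delimiter)
    # decimal comma only plausible in regional semicolon exports
    return reader, delimiter == ";"


def _require_columns(found: Sequence[str] | None, required: Sequence[str]) -> None:
    found = found or []
    missing = [c for c in required if c not in found]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")


def read_specimens(
    path: str | Path, delimiter: str | None = None
) -> list[SpecimenRecord]:
    """Read and validate specimen records from a delimited text file.

    Columns: ``specimen_id, species, sex, total_length_mm, total_weight_g,
    gutted_weight_g, stomach_weight_g, capture_date, interval, repletion``.
    Delimiter is auto-detected among comma/semicolon/tab unless given;
    decimal commas are accepted in semicolon-delimited files.  Rows are
    validated against the domain invariants; errors cite the 1-based data
    row number.
    """
    reader, decimal_comma = _open_rows(path, delimiter)
    _require_columns(reader.fieldnames, SPECIMEN_COLUMNS)
    records: list[SpecimenRecord] = []
    seen_ids: set[str] = set()
    for i, row in enumerate(reader, start=1):
        try:
            rec = SpecimenRecord(
                specimen_id=row["specimen_id"].strip(),
                species=row["species"].strip(),
                sex=row["sex"].strip(),
                total_length=_parse_float(row["total_length_mm"], decimal_comma),
                total_weight=_parse_float(row["total_weight_g"], decimal_comma),
                gutted_weight=_parse_float(row["gutted_weight_g"], decimal_comma),
                stomach_weight=_parse_float(row["stomach_weight_g"], decimal_comma),
                capture_date=dt.date.fromisoformat(row["capture_date"].strip()),
                interval=row["interval"].strip(),
                repletion=row["repletion"].strip(),
            )
        except RecordError as exc:
            raise RecordError(str(exc), row=i) from None
        except (KeyError, ValueError) as exc:
            raise RecordError(f"unparseable row: {exc}", row=i) from None
        if rec.specimen_id in seen_ids:
            raise RecordError(f"duplicate specimen_id {rec.specimen_id!r}", row=i)
        seen_ids.add(rec.specimen_id)
        records.append(rec)
    return records


def read_stomach_items(
    path: str | Path,
    specimens: Sequence[SpecimenRecord],
    delimiter: str | None = None,
) -> list[StomachItem]:
    """Read stomach-content items and validate them against the specimens.

    Every ``specimen_id`` must resolve to a known specimen, and specimens
    recorded as void may not carry content rows.
    """
    by_id = {s.specimen_id: s for s in specimens}
    reader, decimal_comma = _open_rows(path, delimiter)
    _require_columns(reader.fieldnames, ITEM_COLUMNS)
    items: list[StomachItem] = []
    for i, row in enumerate(reader, start=1):
        sid = row["specimen_id"].strip()
        if sid not in by_id:
            raise RecordError(f"unknown specimen_id {sid!r}", row=i)
        try:
            item = StomachItem(
                specimen_id=sid,
                category=row["category"].strip(),
                volume=_parse_float(row["volume"], decimal_comma),
            )
        except RecordError as exc:
            raise RecordError(str(exc), row=i) from None
        except (KeyError, ValueError) as exc:
            raise RecordError(f"unparseable row: {exc}", row=i) from None
        if by_id[sid].repletion == "void":
            raise RecordError(
                f"specimen {sid!r} is void but has a content row", row=i
            )
        items.append(item)
    return items


def write_specimens(records: Iterable[SpecimenRecord], path: str | Path) -> None:
    """Write specimen records as UTF-8 CSV ("." decimal, header row)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(SPECIMEN_COLUMNS)
        for r in records:
            w.writerow(
                [
                    r.specimen_id, r.species, r.sex,
                    repr(r.total_length), repr(r.total_weight),
                    repr(r.gutted_weight), repr(r.stomach_weight),
                    r.capture_date.isoformat(), r.interval, r.repletion,
                ]
            )


def write_stomach_items(items: Iterable[StomachItem], path: str | Path) -> None:
    """Write stomach-content items as UTF-8 CSV."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(ITEM_COLUMNS)
        for it in items:
            w.writerow([it.specimen_id, it.category, repr(it.volume)])
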