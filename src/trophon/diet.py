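"""Diet composition tables: occurrence, volumetric and feeding-importance indices.

For a group of specimens (typically one species in one season) with N
content-bearing stomachs:

* frequency of occurrence   FO_i = 100 * n_i / N, where n_i is the number of
  stomachs containing category i (counted once per stomach);
* volumetric frequency      VF_i = 100 * (total volume of i pooled across the
  group's stomachs) / (total volume of all items);
* index of feeding importance (Kawakami-Vazzoler)
                            IF_i = FO_i * VF_i / sum_j FO_j * VF_j.

IF_i is invariant to any positive rescaling of the raw volumes, so the unit
in which item volumes were measured never matters as long as it is
consistent within the sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .core_data import (
    CATEGORIES,
    REPLETION_CLASSES,
    EmptyGroupError,
    GroupKey,
    SchemaError,
    SpecimenRecord,
    StomachItem,
    group_keys,
    select_specimens,
)

__all__ = [
    "DietRow",
    "DietTable",
    "RepletionProfile",
    "frequency_of_occurrence",
    "volumetric_frequency",
    "feeding_importance",
    "repletion_profile",
    "diet_table",
    "diet_tables",
    "diet_frame",
]


@dataclass(frozen=True)
class DietRow:
    """Per-category entries of a diet table."""

    n_occurrences: int
    fo: float  # percent of content-bearing stomachs, [0, 100]
    vf: float  # percent of pooled volume, [0, 100]
    ifi: float  # feeding-importance proportion, [0, 1]


@dataclass(frozen=True)
class DietTable:
    """FO/VF/IF_i per food category for one specimen group."""

    group: GroupKey
    n_stomachs_with_content: int
    rows: Mapping[str, DietRow]

    def utilization(self, measure: str = "vf") -> dict[str, float]:
        """Per-category utilization values under the chosen measure."""
        if measure not in ("vf", "fo", "ifi"):
            raise SchemaError(f"measure {measure!r} not one of vf/fo/ifi")
        return {c: getattr(r, measure) for c, r in self.rows.items()}


@dataclass(frozen=True)
class RepletionProfile:
    """Counts and relative frequencies of stomach repletion classes."""

    group: GroupKey
    counts: Mapping[str, int]
    rel_freq: Mapping[str, float]


def _content_stomachs(
    items: Iterable[StomachItem],
    specimens: Iterable[SpecimenRecord],
    group: GroupKey,
) -> tuple[list[SpecimenRecord], dict[str, list[StomachItem]]]:
    """Group specimens with >=1 item and repletion != void, plus their items."""
    selected = select_specimens(specimens, group)
    by_id: dict[str, list[StomachItem]] = {s.specimen_id: [] for s in selected}
    for it in items:
        if it.specimen_id in by_id:
            by_id[it.specimen_id].append(it)
    content = [
        s for s in selected if s.repletion != "void" and by_id[s.specimen_id]
    ]
    return content, by_id


def frequency_of_occurrence(
    items: Iterable[StomachItem],
    specimens: Iterable[SpecimenRecord],
    group: GroupKey,
    categories: Sequence[str] = CATEGORIES,
) -> dict[str, float]:
    """FO_i = 100 * n_i / N per category; absent categories report 0."""
    content, by_id = _content_stomachs(items, specimens, group)
    n_total = len(content)
    if n_total == 0:
        raise EmptyGroupError(f"no content-bearing stomachs in group {group}")
    fo = {}
    for cat in categories:
        n_i = sum(
            1 for s in content
            if any(it.category == cat for it in by_id[s.specimen_id])
        )
        fo[cat] = 100.0 * n_i / n_total
    return fo


def volumetric_frequency(
    items: Iterable[StomachItem],
    specimens: Iterable[SpecimenRecord],
    group: GroupKey,
    categories: Sequence[str] = CATEGORIES,
) -> dict[str, float]:
    """VF_i as a category's percent share of the group's pooled item volume."""
    content, by_id = _content_stomachs(items, specimens, group)
    if not content:
        raise EmptyGroupError(f"no content-bearing stomachs in group {group}")
    totals = dict.fromkeys(categories, 0.0)
    for s in content:
        for it in by_id[s.specimen_id]:
            totals[it.category] = totals.get(it.category, 0.0) + it.volume
    grand = sum(totals.values())
    if grand <= 0:
        raise EmptyGroupError(f"all item volumes are zero in group {group}")
    return {c: 100.0 * totals.get(c, 0.0) / grand for c in categories}


def feeding_importance(
    fo: Mapping[str, float], vf: Mapping[str, float]
) -> dict[str, float]:
    """IF_i = FO_i * VF_i / sum_j FO_j * VF_j over the shared category keys."""
    if set(fo) != set(vf):
        raise SchemaError(
            f"FO and VF category keys differ: {sorted(set(fo) ^ set(vf))}"
        )
    products = {c: fo[c] * vf[c] for c in fo}
    denom = sum(products.values())
    if denom <= 0:
        raise EmptyGroupError("all FO*VF products are zero")
    return {c: p / denom for c, p in products.items()}


def repletion_profile(
    specimens: Iterable[SpecimenRecord], group: GroupKey
) -> RepletionProfile:
    """Counts and relative frequencies of void/partly_full/full stomachs."""
    selected = select_specimens(specimens, group)
    if not selected:
        raise EmptyGroupError(f"no specimens in group {group}")
    counts = dict.fromkeys(REPLETION_CLASSES, 0)
    for s in selected:
        counts[s.repletion] += 1
    total = len(selected)
    rel = {k: v / total for k, v in counts.items()}
    return RepletionProfile(group=group, counts=counts, rel_freq=rel)


def diet_table(
    items: Iterable[StomachItem],
    specimens: Iterable[SpecimenRecord],
    group: GroupKey,
    categories: Sequence[str] = CATEGORIES,
) -> DietTable:
    """Assemble FO, VF and IF_i (sharing one N) into a diet table."""
    items = list(items)
    specimens = list(specimens)
    content, by_id = _content_stomachs(items, specimens, group)
    fo = frequency_of_occurrence(items, specimens, group, categories)
    vf = volumetric_frequency(items, specimens, group, categories)
    ifi = feeding_importance(fo, vf)
    rows = {}
    for cat in categories:
        n_i = sum(
            1 for s in content
            if any(it.category == cat for it in by_id[s.specimen_id])
        )
        rows[cat] = DietRow(n_occurrences=n_i, fo=fo[cat], vf=vf[cat], ifi=ifi[cat])
    return DietTable(
        group=group, n_stomachs_with_content=len(content), rows=rows
    )


def diet_tables(
    items: Iterable[StomachItem],
    specimens: Iterable[SpecimenRecord],
    by: Sequence[str] = ("species", "season"),
    categories: Sequence[str] = CATEGORIES,
) -> list[DietTable]:
    """One diet table per observed group along the requested axes.

    Groups with no content-bearing stomachs are skipped.
    """
    items = list(items)
    specimens = list(specimens)
    tables = []
    for key in group_keys(specimens, by=by):
        try:
            tables.append(diet_table(items, specimens, key, categories))
        except EmptyGroupError:
            continue
    return tables


def diet_frame(tables: Iterable[DietTable]) -> pd.DataFrame:
    """Long-format DataFrame of diet tables (presentation rounding applied).

    FO/VF are rounded to 3 decimals and IF_i to 4, the conventional
    reporting precision; the DietTable objects keep full precision.
    """
    rows = []
    for t in tables:
        for cat, r in t.rows.items():
            rows.append(
                {
                    "species": t.group.species,
                    "season": t.group.season,
                    "interval": t.group.interval,
                    "category": cat,
                    "n": r.n_occurrences,
                    "N": t.n_stomachs_with_content,
                    "fo_pct": round(r.fo, 3),
                    "vf_pct": round(r.vf, 3),
                    "ifi": round(r.ifi, 4),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "species", "season", "interval", "category",
            "n", "N", "fo_pct", "vf_pct", "ifi",
        ],
    )
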