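"""Trophic niche breadth (Levins, standardized) and pairwise overlap (Pianka).

Both indices operate on utilization vectors p over a fixed set of resource
states (here, the six broad food categories), normalised to proportions:

* Levins breadth        B  = 1 / sum_j p_j^2,  Bi = (B - 1) / (n - 1)
  with n the number of resource states; Bi = 0 for a single-resource diet
  and Bi = 1 for uniform use of all n states.
* Pianka overlap        O_jk = sum_i p_ij p_ik /
                               sqrt(sum_i p_ij^2 * sum_i p_ik^2)
  which runs from 0 (disjoint resource use) to 1 (proportionally identical
  diets) and is symmetric in the two species.

Values are banded low (< 0.4), moderate (0.4-0.6, boundaries inclusive) or
high (> 0.6).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .core_data import SchemaError
from .diet import DietTable

__all__ = [
    "UtilizationMatrix",
    "NicheClassification",
    "levins_breadth",
    "pianka_overlap",
    "classify_niche",
]


@dataclass(frozen=True)
class UtilizationMatrix:
    """Species-by-resource utilization proportions.

    Rows are species (or species x season groups), columns resource
    categories.  Entries are nonnegative; every row must have positive sum.
    ``normalized`` divides each row by its row sum.
    """

    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 2:
            raise SchemaError("utilization matrix must be 2-D")
        if arr.shape != (len(self.row_labels), len(self.col_labels)):
            raise SchemaError(
                f"shape {arr.shape} does not match labels "
                f"({len(self.row_labels)}, {len(self.col_labels)})"
            )
        if np.any(arr < 0):
            raise SchemaError("utilization entries must be >= 0")
        if np.any(arr.sum(axis=1) <= 0):
            raise SchemaError("every row must have positive sum")
        object.__setattr__(self, "values", arr)

    @property
    def normalized(self) -> np.ndarray:
        return self.values / self.values.sum(axis=1, keepdims=True)

    def row(self, label: str) -> np.ndarray:
        return self.values[self.row_labels.index(label)]

    @classmethod
    def from_diet_tables(
        cls, tables: Iterable[DietTable], measure: str = "vf"
    ) -> "UtilizationMatrix":
        """Build a matrix from diet tables using FO, VF or IF_i utilization.

        Volume share (``vf``) is the default utilization measure; ``fo`` and
        ``ifi`` are available for sensitivity analyses.  Row labels are
        "species" or "species/season" depending on the tables' grouping.
        """
        tables = list(tables)
        if not tables:
            raise SchemaError("no diet tables supplied")
        cols = tuple(tables[0].rows.keys())
        rows, labels = [], []
        for t in tables:
            if tuple(t.rows.keys()) != cols:
                raise SchemaError("diet tables use different category schemes")
            util = t.utilization(measure)
            rows.append([util[c] for c in cols])
            label = t.group.species
            if t.group.season != "all":
                label += f"/{t.group.season}"
            if t.group.interval != "all":
                label += f"@{t.group.interval}"
            labels.append(label)
        return cls(
            row_labels=tuple(labels), col_labels=cols, values=np.array(rows)
        )


@dataclass(frozen=True)
class NicheClassification:
    """An index value in [0, 1] with its low/moderate/high band."""

    value: float
    band: str


def _as_proportions(row: Sequence[float]) -> np.ndarray:
    p = np.asarray(row, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("utilization row must be a non-empty 1-D vector")
    if np.any(p < 0):
        raise ValueError("utilization values must be >= 0")
    total = p.sum()
    if total <= 0:
        raise ValueError("utilization row sums to zero")
    return p / total


def levins_breadth(row: Sequence[float], n_states: int | None = None) -> float:
    """Levins standardized niche breadth Bi = (1/sum p^2 - 1)/(n - 1).

    ``n_states`` defaults to the length of the utilization vector (the fixed
    resource scheme), which keeps Bi comparable across groups that happen
    not to use every category; it must be >= 2 and at least the number of
    nonzero entries.
    """
    p = _as_proportions(row)
    if n_states is None:
        n_states = p.size
    if n_states < 2:
        raise ValueError("n_states must be >= 2")
    if n_states < int(np.count_nonzero(p)):
        raise ValueError(
            f"n_states={n_states} below the {np.count_nonzero(p)} resources used"
        )
    b = 1.0 / float(np.sum(p * p))
    return (b - 1.0) / (n_states - 1.0)


def pianka_overlap(row_j: Sequence[float], row_k: Sequence[float]) -> float:
    """Pianka's symmetric niche overlap between two utilization vectors."""
    pj = _as_proportions(row_j)
    pk = _as_proportions(row_k)
    if pj.size != pk.size:
        raise ValueError("utilization vectors must share the category set")
    num = float(np.dot(pj, pk))
    den = float(np.sqrt(np.dot(pj, pj) * np.dot(pk, pk)))
    return num / den


def classify_niche(value: float) -> NicheClassification:
    """Band an index in [0, 1] as low (<0.4), moderate (0.4-0.6) or high (>0.6)."""
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"index value {value} outside [0, 1]")
    if value < 0.4:
        band = "low"
    elif value <= 0.6:
        band = "moderate"
    else:
        band = "high"
    return NicheClassification(value=value, band=band)
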