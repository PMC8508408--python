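"""Data cleaning: drop veterinary contaminants and collapse near-duplicate
top-tier hospital points.

Duplicate collapse applies only within the 3A-hospital category: points
connected by chains of pairwise great-circle distances <= radius (default
200 m, inclusive) form one group — single-linkage connected components, the
unique order-independent reading of "grouped into one data point". The
representative kept is the group member with the lexicographically smallest
id, so output rows are always real input records and the operation is
deterministic under row reordering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._geo import haversine_m
from .errors import ConfigurationError
from .grading import ANIMAL_CATEGORY, categorize, load_synonyms

logger = logging.getLogger(__name__)

LEVEL1_CATEGORY = "3a hospital"


@dataclass
class CleaningReport:
    n_input: int
    n_animal_removed: int
    n_duplicates_removed: int
    duplicate_groups: list[tuple[str, list[str]]] = field(default_factory=list)

    @property
    def n_valid(self) -> int:
        return self.n_input - self.n_animal_removed - self.n_duplicates_removed

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"quantity": ["n_input", "n_animal_removed", "n_duplicates_removed",
                          "n_valid"],
             "count": [self.n_input, self.n_animal_removed,
                       self.n_duplicates_removed, self.n_valid]})


def remove_animal_facilities(records: pd.DataFrame,
                             synonyms: dict[str, str] | None = None,
                             ) -> tuple[pd.DataFrame, int]:
    """Drop records whose category resolves to the animal-medical
    contaminant; returns (kept records, number removed)."""
    if records.empty:
        return records, 0
    synonyms = synonyms if synonyms is not None else load_synonyms()
    is_animal = categorize(records, synonyms) == ANIMAL_CATEGORY
    removed = int(is_animal.sum())
    logger.info("removed %d animal-medical records", removed)
    return records.loc[~is_animal].reset_index(drop=True), removed


class _UnionFind:
    def __init__(self, n: int):
        self.parent = np.arange(n)

    def find(self, i: int) -> int:
        parent = self.parent
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[ri] = rj


def _grouping(lon: np.ndarray, lat: np.ndarray, radius_m: float) -> np.ndarray:
    """Single-linkage connected-component labels under haversine <= radius.

    Candidate pairs are restricted to neighbouring cells of a lat/lon grid
    slightly coarser than the radius, which bounds the pairwise work without
    changing the result (any pair within the radius shares adjacent cells).
    """
    n = len(lon)
    uf = _UnionFind(n)
    # grid pitch: radius expressed in degrees, padded for longitude shrink
    lat_pitch = radius_m / 111_000.0
    coslat = max(np.cos(np.radians(np.abs(lat).max() if n else 0.0)), 1e-6)
    lon_pitch = lat_pitch / coslat
    cells: dict[tuple[int, int], list[int]] = {}
    ix = np.floor(lon / lon_pitch).astype(int)
    iy = np.floor(lat / lat_pitch).astype(int)
    for i in range(n):
        cells.setdefault((ix[i], iy[i]), []).append(i)
    for (cx, cy), members in cells.items():
        neighbours: list[int] = []
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                neighbours.extend(cells.get((cx + dx, cy + dy), ()))
        if not neighbours:
            continue
        nb = np.asarray(neighbours)
        for i in members:
            d = haversine_m(lon[i], lat[i], lon[nb], lat[nb])
            for j in nb[d <= radius_m]:
                uf.union(i, int(j))
    return np.asarray([uf.find(i) for i in range(n)])


def dedupe_level1(records: pd.DataFrame, radius_m: float = 200.0,
                  synonyms: dict[str, str] | None = None,
                  ) -> tuple[pd.DataFrame, CleaningReport]:
    """Collapse chained 3A-hospital points within ``radius_m`` metres.

    Non-3A categories are untouched. Returns the deduplicated table and a
    CleaningReport fragment (n_animal_removed = 0) listing every multi-member
    group as (representative id, member ids).
    """
    if radius_m <= 0:
        raise ConfigurationError("dedup radius must be positive")
    report = CleaningReport(n_input=len(records), n_animal_removed=0,
                            n_duplicates_removed=0)
    if records.empty:
        return records, report

    synonyms = synonyms if synonyms is not None else load_synonyms()
    is_l1 = (categorize(records, synonyms) == LEVEL1_CATEGORY).to_numpy()
    l1 = records.loc[is_l1]
    if l1.empty:
        return records.reset_index(drop=True), report

    labels = _grouping(l1["longitude"].to_numpy(float),
                       l1["latitude"].to_numpy(float), radius_m)
    l1_ids = l1["id"].to_numpy()
    keep_ids: set[str] = set()
    for lab in np.unique(labels):
        member_ids = sorted(l1_ids[labels == lab])
        keep_ids.add(member_ids[0])
        if len(member_ids) > 1:
            report.duplicate_groups.append((member_ids[0], member_ids))
            if l1.loc[l1["id"].isin(member_ids), "city_code"].nunique() > 1:
                logger.warning("duplicate group %s spans multiple cities "
                               "(distance rule only)", member_ids[0])
    drop = is_l1 & ~records["id"].isin(keep_ids).to_numpy()
    report.n_duplicates_removed = int(drop.sum())
    logger.info("collapsed %d duplicate 3A points in %d groups",
                report.n_duplicates_removed, len(report.duplicate_groups))
    return records.loc[~drop].reset_index(drop=True), report


def clean(records: pd.DataFrame, radius_m: float = 200.0,
          synonyms: dict[str, str] | None = None,
          ) -> tuple[pd.DataFrame, CleaningReport]:
    """Full cleaning stage: animal removal followed by 3A deduplication."""
    synonyms = synonyms if synonyms is not None else load_synonyms()
    n_input = len(records)
    kept, n_animal = remove_animal_facilities(records, synonyms)
    deduped, frag = dedupe_level1(kept, radius_m, synonyms)
    return deduped, CleaningReport(
        n_input=n_input, n_animal_removed=n_animal,
        n_duplicates_removed=frag.n_duplicates_removed,
        duplicate_groups=frag.duplicate_groups)
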