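"""Grading of institution categories into three weighted levels.

The raw feed carries ~24 subcategory labels; these are first collapsed onto
8 canonical analysis categories through an editable synonym table, then each
canonical category maps to a level i in {1, 2, 3} with Delphi-elicited
weights (default 0.6 / 0.3 / 0.1). Weights play no role here beyond scheme
validation — they enter only in scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import pandas as pd
import yaml

from .errors import ConfigurationError, UnclassifiableCategoryError

ANIMAL_CATEGORY = "animal medical"

CANONICAL_CATEGORIES = (
    "3a hospital", "general hospital", "specialized hospital",
    "disease prevention institution", "first aid center",
    "rural hospital", "clinic", "pharmacy",
)


def _norm(label: str) -> str:
    return str(label).strip().casefold()


def load_synonyms(path=None) -> dict[str, str]:
    """Raw-label -> canonical-category map (all keys/values case-folded)."""
    if path is None:
        src = resources.files("mrscore.data") / "category_synonyms.yaml"
        raw = yaml.safe_load(src.read_text(encoding="utf-8"))
    else:
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
    table: dict[str, str] = {}
    for canonical, labels in raw.items():
        canonical = _norm(canonical)
        if canonical not in CANONICAL_CATEGORIES and canonical != ANIMAL_CATEGORY:
            raise ConfigurationError(f"unknown canonical category {canonical!r}")
        for label in labels:
            table[_norm(label)] = canonical
    return table


def canonical_category(subcategory, major_category, synonyms: dict[str, str]) -> str | None:
    """Resolve a record's canonical category: subcategory first, then major."""
    return synonyms.get(_norm(subcategory)) or synonyms.get(_norm(major_category))


def categorize(records: pd.DataFrame, synonyms: dict[str, str] | None = None) -> pd.Series:
    """Canonical category per record (NaN where no synonym matches)."""
    synonyms = synonyms if synonyms is not None else load_synonyms()
    sub = records["subcategory"].map(lambda s: synonyms.get(_norm(s)))
    major = records["major_category"].map(lambda s: synonyms.get(_norm(s)))
    return sub.fillna(major)


@dataclass(frozen=True)
class GradingScheme:
    """Category -> level and level -> weight mapping."""

    level_of_category: dict[str, int]
    weight_of_level: dict[int, float]
    synonyms: dict[str, str] = field(default_factory=load_synonyms, repr=False)

    def __post_init__(self):
        weights = self.weight_of_level
        if set(weights) != {1, 2, 3}:
            raise ConfigurationError("weights must be given for levels 1, 2, 3")
        if any(w <= 0 for w in weights.values()):
            raise ConfigurationError("level weights must be strictly positive")
        if abs(sum(weights.values()) - 1.0) > 1e-12:
            raise ConfigurationError("level weights must sum to 1")
        if not set(self.level_of_category.values()) <= {1, 2, 3}:
            raise ConfigurationError("levels must be in {1, 2, 3}")

    @classmethod
    def from_yaml(cls, path=None) -> "GradingScheme":
        if path is None:
            src = resources.files("mrscore.data") / "grading_scheme.yaml"
            raw = yaml.safe_load(src.read_text(encoding="utf-8"))
        else:
            with open(path, encoding="utf-8") as fh:
                raw = yaml.safe_load(fh)
        level_of = {_norm(cat): int(lvl)
                    for lvl, cats in raw["levels"].items() for cat in cats}
        weights = {int(k): float(v) for k, v in raw["weights"].items()}
        return cls(level_of_category=level_of, weight_of_level=weights)

    @classmethod
    def default(cls) -> "GradingScheme":
        return cls.from_yaml()

    def assign_level(self, record) -> int:
        """Level index for one record (a mapping with subcategory /
        major_category fields); raises UnclassifiableCategoryError for
        labels outside the scheme (e.g. veterinary contaminants)."""
        cat = canonical_category(record["subcategory"], record["major_category"],
                                 self.synonyms)
        if cat is None or cat not in self.level_of_category:
            raise UnclassifiableCategoryError(
                f"{record['subcategory']} / {record['major_category']}")
        return self.level_of_category[cat]


@dataclass(frozen=True)
class LevelTally:
    """Per-city and dataset-wide institution counts by level.

    ``by_city``: DataFrame indexed by city_code with integer columns 1, 2, 3.
    ``totals``: level -> dataset-wide count. ``shares_pct``: level -> share of
    the valid total, in percent rounded to 2 decimals (NaN on empty input).
    """

    by_city: pd.DataFrame
    totals: dict[int, int]
    shares_pct: dict[int, float]

    @property
    def n_total(self) -> int:
        return int(sum(self.totals.values()))


def level_shares(totals: dict[int, int]) -> dict[int, float]:
    """Level shares of the valid total, percent rounded to 2 decimals."""
    n = sum(totals.values())
    if n == 0:
        return {lvl: float("nan") for lvl in totals}
    return {lvl: round(100.0 * c / n, 2) for lvl, c in totals.items()}


def tally_levels(records: pd.DataFrame, scheme: GradingScheme | None = None) -> LevelTally:
    """Count classifiable records per city and level.

    Every record must be classifiable; contaminants are expected to have
    been removed by preprocessing and raise UnclassifiableCategoryError.
    """
    scheme = scheme or GradingScheme.default()
    if records.empty:
        empty = pd.DataFrame(columns=[1, 2, 3], dtype=int)
        empty.index.name = "city_code"
        return LevelTally(by_city=empty, totals={1: 0, 2: 0, 3: 0},
                          shares_pct={1: float("nan"), 2: float("nan"), 3: float("nan")})

    cats = categorize(records, scheme.synonyms)
    bad = cats.isna() | ~cats.isin(scheme.level_of_category)
    if bad.any():
        labels = (records.loc[bad, "subcategory"].astype(str) + " / "
                  + records.loc[bad, "major_category"].astype(str))
        raise UnclassifiableCategoryError(labels.tolist())

    levels = cats.map(scheme.level_of_category).astype(int)
    by_city = (pd.crosstab(records["city_code"], levels)
               .reindex(columns=[1, 2, 3], fill_value=0))
    by_city.index.name = "city_code"
    totals = {lvl: int(by_city[lvl].sum()) for lvl in (1, 2, 3)}
    return LevelTally(by_city=by_city, totals=totals,
                      shares_pct=level_shares(totals))
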