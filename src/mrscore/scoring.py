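"""Per-level scores and the composite city medical-resource score (MRSc).

For levels 1 and 2 a city's score is its institution count divided by the
national maximum city count at that level. Level 3 institutions (primary
care: rural hospitals, clinics, pharmacies) are so numerous that raw counts
track population; the level-3 score is therefore per capita, normalized by
the per-capita rate of the *reference* city — the city holding the maximum
raw level-3 count — so the reference city scores exactly 1 while cities
with a higher per-capita rate may legitimately exceed 1.

The composite is the weight-combined sum of the three level scores, reported
on a 0-100 display scale (raw weighted values are retained in ``mrsc_raw``).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import CompositionError, NumericalError, ValidationError
from .grading import GradingScheme, LevelTally

#: multiplier taking raw weighted scores onto the display scale
DISPLAY_SCALE = 100.0


@dataclass(frozen=True)
class ReferenceCity:
    """City achieving the maximum count at one level (ties: smallest
    city_code), with its population where the level is per capita."""
    level: int
    city_code: str
    count: int
    population: float | None = None


def _max_count_city(counts: pd.Series) -> tuple[str, int]:
    top = counts.max()
    if top <= 0:
        raise NumericalError("all counts are zero at this level; score undefined")
    # deterministic tie-break: smallest city_code among the argmax set
    code = min(counts.index[counts == top])
    return str(code), int(top)


def level_score_count(tally: LevelTally, level: int) -> pd.Series:
    """Count-normalized score for level 1 or 2: count / max city count."""
    if level not in (1, 2):
        raise ValueError("count-normalized scores apply to levels 1 and 2")
    counts = tally.by_city[level]
    _, top = _max_count_city(counts)
    return (counts / top).rename(f"s{level}")


def level_score_percapita(tally: LevelTally, populations: pd.Series,
                          level: int = 3) -> tuple[pd.Series, ReferenceCity]:
    """Per-capita score for level 3.

    score(city) = (count / population) / (ref_count / ref_population) where
    the reference is the city with the maximum raw count at this level.
    """
    counts = tally.by_city[level]
    populations = populations.reindex(counts.index)
    if populations.isna().any() or (populations <= 0).any():
        missing = counts.index[populations.isna() | (populations <= 0)].tolist()
        raise ValidationError(f"missing/non-positive population for: {missing[:10]}")
    ref_code, ref_count = _max_count_city(counts)
    ref_pop = float(populations.loc[ref_code])
    ref_rate = ref_count / ref_pop
    score = (counts / populations) / ref_rate
    return score.rename(f"s{level}"), ReferenceCity(level, ref_code, ref_count, ref_pop)


def compose_mrsc(s1: pd.Series, s2: pd.Series, s3: pd.Series,
                 cities: pd.DataFrame,
                 scheme: GradingScheme | None = None) -> pd.DataFrame:
    """Combine level scores into the composite MRSc with ranks.

    ``cities`` must be indexed or keyed by city_code and provide
    province_name, city_name and an ``excluded`` flag; excluded cities are
    dropped before ranking. National/provincial ranks use dense "min" ties
    (equal scores share a rank) and rows are ordered by rank then city_code.
    """
    scheme = scheme or GradingScheme.default()
    meta = cities.set_index("city_code") if "city_code" in cities.columns else cities

    scores = pd.concat([s1.rename("s1"), s2.rename("s2"), s3.rename("s3")], axis=1)
    for col in ("s1", "s2", "s3"):
        if scores[col].isna().any():
            missing = scores.index[scores[col].isna()].tolist()
            raise CompositionError(f"missing level {col[1]} score for: {missing[:10]}")

    w = scheme.weight_of_level
    scores["mrsc_raw"] = (w[1] * scores["s1"] + w[2] * scores["s2"]
                          + w[3] * scores["s3"])
    scores["mrsc"] = DISPLAY_SCALE * scores["mrsc_raw"]

    out = scores.join(meta[["province_name", "city_name"]], how="left")
    if "excluded" in meta.columns:
        out = out.loc[~meta["excluded"].reindex(out.index).fillna(False).astype(bool)]
    out.index.name = "city_code"
    out = out.reset_index()
    out["national_rank"] = out["mrsc"].rank(method="min", ascending=False).astype(int)
    out["provincial_rank"] = (out.groupby("province_name")["mrsc"]
                              .rank(method="min", ascending=False).astype(int))
    return (out.sort_values(["national_rank", "city_code"])
            .reset_index(drop=True))


def score_cities(tally: LevelTally, cities: pd.DataFrame,
                 scheme: GradingScheme | None = None,
                 ) -> tuple[pd.DataFrame, dict[int, ReferenceCity]]:
    """End-to-end scoring from a level tally and a city attribute table.

    Cities present in the attribute table but absent from the tally count as
    zero institutions at every level. Returns the score table and the
    reference city per level.
    """
    scheme = scheme or GradingScheme.default()
    meta = cities.set_index("city_code")
    if "excluded" in meta.columns:
        # excluded units never enter normalization maxima or ranks
        meta = meta.loc[~meta["excluded"].astype(bool)]
    tally = LevelTally(
        by_city=tally.by_city.reindex(meta.index, fill_value=0),
        totals=tally.totals, shares_pct=tally.shares_pct)
    refs: dict[int, ReferenceCity] = {}
    s1 = level_score_count(tally, 1)
    refs[1] = ReferenceCity(1, *_max_count_city(tally.by_city[1]))
    s2 = level_score_count(tally, 2)
    refs[2] = ReferenceCity(2, *_max_count_city(tally.by_city[2]))
    s3, refs[3] = level_score_percapita(tally, meta["population"])
    return compose_mrsc(s1, s2, s3, cities, scheme), refs
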