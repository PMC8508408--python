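"""Equity statistics over city scores: the provincial primacy ratio and
mean / coefficient-of-variation summaries by sector, economic zone and
province.

The primacy ratio R is the composite score of a province's top ("primate")
city divided by that of its second city. R close to 1 indicates a balanced
provincial structure; R >= 2.0 (inclusive) flags over-concentration of
resources in the primate city. The primate city is defined purely by score,
not by administrative (capital) status.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

OVER_CONCENTRATION_THRESHOLD = 2.0


@dataclass(frozen=True)
class PrimacyResult:
    province: str
    primate_city: str | None
    secondary_city: str | None
    ratio: float
    applicable: bool = True

    @property
    def over_concentrated(self) -> bool:
        return self.applicable and self.ratio >= OVER_CONCENTRATION_THRESHOLD


def primacy_ratio(scores: pd.DataFrame, province: str) -> PrimacyResult:
    """Primacy ratio for one province from a score table with columns
    province_name, city_name, mrsc. Provinces with fewer than two scored
    cities (municipalities, single-unit regions) are not applicable."""
    sub = scores.loc[scores["province_name"] == province]
    if len(sub) < 2:
        logger.info("province %s has %d scored city(ies); primacy ratio "
                    "not applicable", province, len(sub))
        return PrimacyResult(province, None, None, float("nan"), applicable=False)
    top2 = sub.sort_values(["mrsc", "city_name"], ascending=[False, True]).head(2)
    m1, m2 = top2["mrsc"].to_numpy(float)
    return PrimacyResult(province, top2.iloc[0]["city_name"],
                         top2.iloc[1]["city_name"], float(m1 / m2))


def primacy_table(scores: pd.DataFrame) -> pd.DataFrame:
    """Primacy ratios for every applicable province, sorted by descending
    ratio; ``primacy_ratio`` column is rounded to 2 decimals for display."""
    rows = []
    for prov in sorted(scores["province_name"].dropna().unique()):
        res = primacy_ratio(scores, prov)
        if res.applicable:
            rows.append({"province_name": res.province,
                         "primacy_ratio": round(res.ratio, 2),
                         "primate_city": res.primate_city,
                         "secondary_city": res.secondary_city,
                         "over_concentrated": res.over_concentrated})
    return (pd.DataFrame(rows, columns=["province_name", "primacy_ratio",
                                        "primate_city", "secondary_city",
                                        "over_concentrated"])
            .sort_values(["primacy_ratio", "province_name"],
                         ascending=[False, True])
            .reset_index(drop=True))


def primacy_summary(ratios) -> tuple[float, int, int]:
    """(mean ratio to 2 decimals, number over-concentrated, number total).

    Accepts a sequence of ratios, of PrimacyResult, or a primacy_table frame.
    """
    if isinstance(ratios, pd.DataFrame):
        values = ratios["primacy_ratio"].to_numpy(float)
    else:
        values = np.asarray(
            [r.ratio if isinstance(r, PrimacyResult) else float(r)
             for r in ratios], dtype=float)
    values = values[~np.isnan(values)]
    if values.size == 0:
        return float("nan"), 0, 0
    mean = round(float(values.mean()), 2)
    n_over = int((values >= OVER_CONCENTRATION_THRESHOLD).sum())
    return mean, n_over, int(values.size)


def coefficient_of_variation(values, sample: bool = True) -> float:
    """Standard deviation divided by mean; sample (n-1) sd by default."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        return float("nan")
    mean = values.mean()
    if mean == 0:
        return float("nan")
    return float(values.std(ddof=1 if sample else 0) / mean)


def region_summarize(scores: pd.DataFrame, cities: pd.DataFrame,
                     grouping: str, sample_cv: bool = True) -> pd.DataFrame:
    """Per-region unit count, mean score and CV of member-city scores.

    ``grouping`` is one of "sector", "economic_zone", "province". Regions
    with a single unit report CV as NaN (not available). Excluded cities
    never appear in ``scores`` and hence never contribute.
    """
    col = {"sector": "sector", "zone": "economic_zone",
           "economic_zone": "economic_zone", "province": "province_name"}
    if grouping not in col:
        raise ValueError(f"unknown grouping {grouping!r}")
    key = col[grouping]
    meta = cities.set_index("city_code") if "city_code" in cities.columns else cities
    joined = scores.join(meta[[c for c in ("sector", "economic_zone")
                               if c in meta.columns]],
                         on="city_code") if key != "province_name" else scores
    if key != "province_name" and joined[key].isna().any():
        missing = joined.loc[joined[key].isna(), "city_name"].tolist()
        raise ValueError(f"cities without a {grouping} membership: {missing[:10]}")
    out = (joined.groupby(key)["mrsc"]
           .agg(n_units="size", mean_score="mean",
                cv=lambda v: coefficient_of_variation(v, sample=sample_cv))
           .reset_index()
           .rename(columns={key: "region"}))
    return out.sort_values("region").reset_index(drop=True)
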