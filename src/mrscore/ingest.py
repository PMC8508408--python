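"""Reading and validating institution point tables and city attribute tables.

Tables are held as pandas DataFrames with canonical snake_case columns; the
on-disk CSV schema follows the national point-of-interest feed (one row per
facility, with raw category labels and administrative codes). The module
also owns the fixed province -> economic sector / economic zone membership
map used by the aggregate equity summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .errors import SchemaError, ValidationError

logger = logging.getLogger(__name__)

#: CSV header -> canonical column name for the institution table.
INSTITUTION_CSV_COLUMNS = {
    "Id": "id",
    "Medical Institution Name": "name",
    "Hospital Major Category": "major_category",
    "Hospital Subcategory": "subcategory",
    "Longitude": "longitude",
    "Latitude": "latitude",
    "Province Code": "province_code",
    "Province Name": "province_name",
    "City Code": "city_code",
    "City Name": "city_name",
    "District Code": "district_code",
    "District Name": "district_name",
}

CITY_CSV_COLUMNS = {
    "City Code": "city_code",
    "City Name": "city_name",
    "Province Name": "province_name",
    "Population": "population",
    "GDP": "gdp",
}


@dataclass(frozen=True)
class RegionMap:
    """Province -> sector and province -> economic-zone memberships.

    ``excluded`` lists province-level units accepted at ingest but excluded
    from scoring (they follow a separate hospital-rating system).
    """

    sector_of: dict[str, str]
    zone_of: dict[str, str]
    excluded: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        for prov in self.zone_of:
            if prov not in self.sector_of:
                raise ValidationError(f"province {prov!r} has a zone but no sector")

    @property
    def sectors(self) -> dict[str, list[str]]:
        return _invert(self.sector_of)

    @property
    def zones(self) -> dict[str, list[str]]:
        return _invert(self.zone_of)

    @classmethod
    def from_yaml(cls, path) -> "RegionMap":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        sector_of: dict[str, str] = {}
        for sector, provinces in raw["sectors"].items():
            for prov in provinces:
                if prov in sector_of:
                    raise ValidationError(f"province {prov!r} in two sectors")
                sector_of[prov] = sector
        zone_of: dict[str, str] = {}
        for zone, provinces in raw["zones"].items():
            for prov in provinces:
                if prov in zone_of:
                    raise ValidationError(f"province {prov!r} in two zones")
                zone_of[prov] = zone
        return cls(sector_of=sector_of, zone_of=zone_of,
                   excluded=frozenset(raw.get("excluded_provinces", [])))

    @classmethod
    def default(cls) -> "RegionMap":
        with resources.as_file(resources.files("mrscore.data") / "regions.yaml") as p:
            return cls.from_yaml(p)


def _invert(mapping: dict[str, str]) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    for key, group in mapping.items():
        out.setdefault(group, []).append(key)
    return out


def _check_header(found, expected_map, path) -> None:
    missing = [c for c in expected_map if c not in found]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def read_institutions(path) -> pd.DataFrame:
    """Read a facility point table, validating ids and coordinate bounds.

    The header must contain every schema column (order-insensitive; extra
    columns are ignored). Rows with coordinates outside [-180, 180] x
    [-90, 90] or unparsable raise :class:`ValidationError` naming the ids.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    _check_header(df.columns, INSTITUTION_CSV_COLUMNS, path)
    df = df[list(INSTITUTION_CSV_COLUMNS)].rename(columns=INSTITUTION_CSV_COLUMNS)

    if df["id"].duplicated().any():
        dupes = df.loc[df["id"].duplicated(), "id"].tolist()
        raise ValidationError(f"duplicate institution ids: {dupes[:10]}")

    for col in ("longitude", "latitude"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    bad = df["longitude"].isna() | df["latitude"].isna() \
        | ~df["longitude"].between(-180, 180) | ~df["latitude"].between(-90, 90)
    if bad.any():
        raise ValidationError(
            f"invalid coordinates for ids: {df.loc[bad, 'id'].tolist()[:10]}")

    logger.info("read %d institution records from %s", len(df), path)
    return df.reset_index(drop=True)


def write_institutions(df: pd.DataFrame, path) -> None:
    """Write an institution table back in the exact input CSV schema."""
    inverse = {v: k for k, v in INSTITUTION_CSV_COLUMNS.items()}
    df[list(INSTITUTION_CSV_COLUMNS.values())].rename(columns=inverse).to_csv(
        path, index=False, encoding="utf-8")


def read_city_attributes(path, regions: RegionMap | None = None) -> pd.DataFrame:
    """Read city population/GDP attributes and join region memberships.

    Cities in provinces unknown to the region map are kept but flagged
    (``region_known = False``) and carry no sector/zone; cities of excluded
    provinces get ``excluded = True``.
    """
    regions = regions or RegionMap.default()
    path = Path(path)
    df = pd.read_csv(path, dtype={"City Code": str}, encoding="utf-8")
    _check_header(df.columns, CITY_CSV_COLUMNS, path)
    df = df[list(CITY_CSV_COLUMNS)].rename(columns=CITY_CSV_COLUMNS)

    for col in ("population", "gdp"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
        if (df[col].isna() | (df[col] <= 0)).any():
            bad = df.loc[df[col].isna() | (df[col] <= 0), "city_name"].tolist()
            raise ValidationError(f"non-positive {col} for cities: {bad[:10]}")

    return annotate_regions(df, regions)


def annotate_regions(cities: pd.DataFrame, regions: RegionMap | None = None) -> pd.DataFrame:
    """Attach sector / economic_zone / excluded / region_known columns."""
    regions = regions or RegionMap.default()
    cities = cities.copy()
    cities["sector"] = cities["province_name"].map(regions.sector_of)
    cities["economic_zone"] = cities["province_name"].map(regions.zone_of)
    cities["excluded"] = cities["province_name"].isin(regions.excluded)
    cities["region_known"] = cities["sector"].notna() | cities["excluded"]
    unknown = cities.loc[~cities["region_known"], "province_name"].unique()
    if len(unknown):
        logger.warning("provinces with no region membership (flagged): %s",
                       list(unknown))
    return cities
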