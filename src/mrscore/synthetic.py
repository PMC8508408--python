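"""Synthetic city tables and institution point clouds with the statistical
structure the scoring pipeline assumes, plus ground-truth bookkeeping for
testing every downstream stage.

The generator emulates four features of the real national facility feed:

* per-city level-III (primary care) counts positively correlated with
  resident population — Poisson counts around a per-capita rate, with
  multiplicative lognormal noise calibrated in closed form to a target
  Pearson correlation (default 0.81);
* concentration of level-I/II institutions in each province's primate city,
  implemented as a within-province reallocation of expected counts (the
  primate city's population weight is multiplied by ``primate_boost`` and
  weights renormalized), which preserves national level shares exactly in
  expectation;
* near-duplicate level-I points: a configurable fraction of 3A-hospital
  points is cloned at a uniform geodesic offset below 200 m;
* a contaminating "animal medical" category.

The default geography is a 369-unit frame (31 mainland province-level units
with realistic per-province city counts, plus Hong Kong and Macao as
excluded units), so the default dataset matches the study frame of the
national analysis: 369 units ingested, 367 scored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._geo import local_offset_deg
from .errors import ConfigurationError
from .ingest import RegionMap, annotate_regions

#: national institution counts by level in the 2019 feed after cleaning
NATIONAL_LEVEL_COUNTS = {1: 1_981, 2: 172_983, 3: 1_001_055}

#: scored city units per mainland province-level unit (2019 study frame);
#: municipalities are single-city units that are simultaneously provinces.
PROVINCE_UNITS_2019 = {
    "Beijing": 1, "Tianjin": 1, "Shanghai": 1, "Chongqing": 1,
    "Hebei": 11, "Shanxi": 11, "Inner Mongolia": 12, "Liaoning": 14,
    "Jilin": 9, "Heilongjiang": 13, "Jiangsu": 13, "Zhejiang": 11,
    "Anhui": 16, "Fujian": 9, "Jiangxi": 11, "Shandong": 16, "Henan": 18,
    "Hubei": 17, "Hunan": 14, "Guangdong": 21, "Guangxi": 14, "Hainan": 19,
    "Sichuan": 21, "Guizhou": 9, "Yunnan": 16, "Tibet": 7, "Shaanxi": 10,
    "Gansu": 14, "Qinghai": 8, "Ningxia": 5, "Xinjiang": 24,
    "Hong Kong": 1, "Macao": 1,
}

_LEVEL_LABELS = {
    1: [("3A Hospital", "3A Hospital")],
    2: [("General hospital", "General hospital"),
        ("Specialized Hospital", "Specialized Hospital"),
        ("Disease Prevention Institution", "Disease Prevention Institution"),
        ("First Aid Center", "First Aid Center")],
    3: [("General hospital", "Rural hospital"),
        ("Clinic", "Clinic"),
        ("Pharmacy", "Pharmacy")],
}
_ANIMAL_LABEL = ("Animal Medical", "Veterinary clinic")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic national dataset.

    Defaults (via :func:`default_config`) reproduce the study conditions of
    the 2019 national analysis: 369 units, per-capita institution rates
    implied by the national level counts, level-III/population correlation
    0.81, duplicate and contaminant loads matching the reported cleaning
    counts.
    """

    n_provinces: int = 8
    cities_per_province: tuple[int, int] = (3, 8)
    seed: int = 42
    pop_lognormal_mu_sigma: tuple[float, float] = (14.80, 0.80)  # log persons
    gdp_elasticity: float = 1.1
    gdp_per_capita: float = 7.0e4          # synthetic currency units / person
    gdp_noise_sigma: float = 0.8           # log scale (per-capita dispersion)
    primate_boost: float = 4.0             # level-I/II weight multiplier
    level1_rate_per_capita: float = 1.46e-6
    level2_rate_per_capita: float = 1.27e-4
    level3_rate_per_capita: float = 7.38e-4
    target_corr: float = 0.81              # level-III count vs population
    dup_fraction: float = 0.63             # clones per level-I point
    animal_fraction: float = 0.027         # contaminants per valid point
    city_scatter_sd: float = 5_000.0       # metres around the city centroid
    province_city_counts: tuple[tuple[str, int], ...] | None = None

    def __post_init__(self):
        for name in ("dup_fraction", "animal_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        for name in ("level1_rate_per_capita", "level2_rate_per_capita",
                     "level3_rate_per_capita", "city_scatter_sd",
                     "gdp_per_capita"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be strictly positive")
        if self.province_city_counts is None:
            if self.n_provinces <= 0:
                raise ConfigurationError("n_provinces must be positive")
            lo, hi = self.cities_per_province
            if lo <= 0 or hi < lo:
                raise ConfigurationError("cities_per_province range invalid")
        if not 0.0 < self.target_corr < 1.0:
            raise ConfigurationError("target_corr must be in (0, 1)")
        if self.primate_boost < 1.0:
            raise ConfigurationError("primate_boost must be >= 1")

    @property
    def level_rates(self) -> dict[int, float]:
        return {1: self.level1_rate_per_capita, 2: self.level2_rate_per_capita,
                3: self.level3_rate_per_capita}

    def count_noise_sigma(self) -> float:
        """Log-sd of the multiplicative noise on level-III rates that yields
        ``target_corr`` between count and population.

        For lognormal populations with log-sd s_p and independent lognormal
        rate noise with log-sd s, corr(pop, pop*noise) =
        sqrt((e^{s_p^2}-1) / (e^{s_p^2+s^2}-1)); inverting gives
        s^2 = ln(1 + (e^{s_p^2}-1)/r^2) - s_p^2.
        """
        sp2 = self.pop_lognormal_mu_sigma[1] ** 2
        s2 = math.log(1.0 + math.expm1(sp2) / self.target_corr ** 2) - sp2
        return math.sqrt(max(s2, 0.0))


def default_config(seed: int = 42) -> SimulationConfig:
    """The calibrated national-scale configuration (369 units)."""
    return SimulationConfig(
        seed=seed,
        province_city_counts=tuple(sorted(PROVINCE_UNITS_2019.items())),
    )


@dataclass
class SyntheticTruth:
    """Ground truth for one generated institution table."""

    counts_by_city: pd.DataFrame          # city_code x levels {1, 2, 3}
    duplicate_ids: list[str] = field(default_factory=list)
    animal_ids: list[str] = field(default_factory=list)

    def n_valid(self) -> int:
        return int(self.counts_by_city.to_numpy().sum())


def _province_frame(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    if config.province_city_counts is not None:
        items = list(config.province_city_counts)
    else:
        lo, hi = config.cities_per_province
        items = [(f"Province {i + 1:02d}", int(rng.integers(lo, hi + 1)))
                 for i in range(config.n_provinces)]
    if any(n <= 0 for _, n in items):
        raise ConfigurationError("every province needs at least one city")
    return pd.DataFrame(items, columns=["province_name", "n_cities"])


def generate_cities(config: SimulationConfig) -> pd.DataFrame:
    """One row per city: codes, names, centroid lon/lat, population, GDP,
    primate flag and region memberships. Deterministic in (seed, config)."""
    rng = np.random.default_rng([config.seed, 0])
    provinces = _province_frame(config, rng)
    n_prov = len(provinces)

    # province centres laid out on a jittered grid inside a country-scale box
    ncols = int(np.ceil(np.sqrt(n_prov)))
    nrows = int(np.ceil(n_prov / ncols))
    gx = np.linspace(82.0, 122.0, ncols)
    gy = np.linspace(24.0, 46.0, max(nrows, 2))[:nrows]
    centers = [(gx[i % ncols], gy[i // ncols]) for i in range(n_prov)]
    jitter = rng.normal(0.0, 0.3, size=(n_prov, 2))

    mu, sigma = config.pop_lognormal_mu_sigma
    rows = []
    for p, (prov, n_cities) in enumerate(provinces.itertuples(index=False)):
        lon0 = centers[p][0] + jitter[p, 0]
        lat0 = centers[p][1] + jitter[p, 1]
        pops = rng.lognormal(mu, sigma, size=n_cities)
        gdp_noise = rng.lognormal(-config.gdp_noise_sigma ** 2 / 2.0,
                                  config.gdp_noise_sigma, size=n_cities)
        lons = lon0 + rng.normal(0.0, 1.0, size=n_cities)
        lats = lat0 + rng.normal(0.0, 0.7, size=n_cities)
        primate = int(np.argmax(pops))
        for c in range(n_cities):
            pop = float(pops[c])
            gdp = (config.gdp_per_capita * 1e6
                   * (pop / 1e6) ** config.gdp_elasticity * float(gdp_noise[c]))
            name = prov if n_cities == 1 else f"{prov} City {c + 1:02d}"
            rows.append({
                "city_code": f"{p + 1:03d}{c + 1:03d}",
                "city_name": name,
                "province_code": f"{p + 1:03d}000",
                "province_name": prov,
                "longitude": float(np.clip(lons[c], -179.9, 179.9)),
                "latitude": float(np.clip(lats[c], -89.0, 89.0)),
                "population": pop,
                "gdp": gdp,
                "is_primate_candidate": c == primate,
            })
    cities = pd.DataFrame(rows)
    return _attach_regions(cities)


def _attach_regions(cities: pd.DataFrame) -> pd.DataFrame:
    """Join the default region map; synthetic province names get assigned
    cyclically to the 4 sectors / 8 zones so every city has a membership."""
    regions = RegionMap.default()
    cities = annotate_regions(cities, regions)
    unknown = sorted(cities.loc[~cities["region_known"], "province_name"].unique())
    if unknown:
        sectors = sorted(set(regions.sector_of.values()))
        zones = sorted(set(regions.zone_of.values()))
        sec_map = {p: sectors[i % len(sectors)] for i, p in enumerate(unknown)}
        zone_map = {p: zones[i % len(zones)] for i, p in enumerate(unknown)}
        mask = ~cities["region_known"]
        cities.loc[mask, "sector"] = cities.loc[mask, "province_name"].map(sec_map)
        cities.loc[mask, "economic_zone"] = cities.loc[mask, "province_name"].map(zone_map)
        cities["region_known"] = True
    return cities


def sample_level_counts(cities: pd.DataFrame, config: SimulationConfig,
                        rng: np.random.Generator) -> pd.DataFrame:
    """Draw true per-city institution counts by level (city_code x {1,2,3}).

    Level 3 is Poisson around rate x population x lognormal noise (noise has
    mean 1; its log-sd comes from the closed-form correlation calibration).
    Levels 1-2 distribute the national expected total over cities with *GDP*
    weights (hospital investment follows the economy, making GDP the
    stronger driver of high-tier institutions and hence of the composite
    score), each province's primate city having its weight multiplied by
    ``primate_boost`` (which concentrates high-tier resources in primate
    cities while leaving the national expectation unchanged); excluded
    units (separate rating system) have no 3A hospitals.
    """
    pop = cities["population"].to_numpy(float)
    gdp = (cities["gdp"].to_numpy(float) if "gdp" in cities else pop.copy())
    counts = pd.DataFrame(0, index=pd.Index(cities["city_code"], name="city_code"),
                          columns=[1, 2, 3])

    s = config.count_noise_sigma()
    noise = rng.lognormal(-s ** 2 / 2.0, s, size=len(cities))
    lam3 = config.level3_rate_per_capita * pop * noise
    counts[3] = rng.poisson(lam3)

    excluded = (cities["excluded"].to_numpy(bool) if "excluded" in cities
                else np.zeros(len(cities), bool))
    w = gdp.copy()
    if "is_primate_candidate" in cities:
        w[cities["is_primate_candidate"].to_numpy(bool)] *= config.primate_boost
    for level in (1, 2):
        lam = config.level_rates[level] * pop.sum() * w / w.sum()
        if level == 1:
            lam[excluded] = 0.0
        counts[level] = rng.poisson(lam)
    return counts


def generate_institutions(cities: pd.DataFrame, config: SimulationConfig,
                          ) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Emit an institution point table for ``cities`` plus ground truth.

    Points scatter isotropically (Gaussian, ``city_scatter_sd`` metres)
    around city centroids. ``dup_fraction`` of level-I points receive a
    clone offset by a uniform geodesic distance < 200 m; ``animal_fraction``
    (of the valid count) contaminant records are added. Deterministic in
    (seed, config).
    """
    if cities.empty:
        raise ConfigurationError("cities table is empty")
    rng = np.random.default_rng([config.seed, 1])
    counts = sample_level_counts(cities, config, rng)
    truth = SyntheticTruth(counts_by_city=counts)

    blocks: list[pd.DataFrame] = []
    serial = 0
    for level in (1, 2, 3):
        n_by_city = counts[level].to_numpy()
        total = int(n_by_city.sum())
        if total == 0:
            continue
        city_idx = np.repeat(np.arange(len(cities)), n_by_city)
        east = rng.normal(0.0, config.city_scatter_sd, size=total)
        north = rng.normal(0.0, config.city_scatter_sd, size=total)
        base_lat = cities["latitude"].to_numpy()[city_idx]
        base_lon = cities["longitude"].to_numpy()[city_idx]
        dlon, dlat = local_offset_deg(base_lat, east, north)
        labels = _LEVEL_LABELS[level]
        pick = rng.integers(0, len(labels), size=total)
        ids = np.array([f"S{serial + k:08d}" for k in range(total)])
        serial += total
        blocks.append(_records(cities, city_idx, ids, pick, labels,
                               base_lon + dlon, base_lat + dlat))

    records = pd.concat(blocks, ignore_index=True)

    # near-duplicate clones of level-I points, geodesic offset < 200 m
    is_l1 = records["subcategory"].eq("3A Hospital").to_numpy()
    l1_pos = np.flatnonzero(is_l1)
    n_dup = int(round(config.dup_fraction * l1_pos.size))
    if n_dup > 0:
        src = rng.choice(l1_pos, size=n_dup, replace=False)
        radius = rng.uniform(5.0, 195.0, size=n_dup)
        bearing = rng.uniform(0.0, 2.0 * np.pi, size=n_dup)
        clones = records.iloc[src].copy().reset_index(drop=True)
        dlon, dlat = local_offset_deg(clones["latitude"].to_numpy(),
                                      radius * np.sin(bearing),
                                      radius * np.cos(bearing))
        clones["longitude"] += dlon
        clones["latitude"] += dlat
        clones["id"] = [f"X{k:08d}" for k in range(n_dup)]
        clones["name"] = clones["name"] + " Annex"
        truth.duplicate_ids = clones["id"].tolist()
        records = pd.concat([records, clones], ignore_index=True)

    # contaminating animal-medical records, scattered like other points
    n_animal = int(round(config.animal_fraction * truth.n_valid()))
    if n_animal > 0:
        pop = cities["population"].to_numpy(float)
        city_idx = rng.choice(len(cities), size=n_animal, p=pop / pop.sum())
        east = rng.normal(0.0, config.city_scatter_sd, size=n_animal)
        north = rng.normal(0.0, config.city_scatter_sd, size=n_animal)
        base_lat = cities["latitude"].to_numpy()[city_idx]
        base_lon = cities["longitude"].to_numpy()[city_idx]
        dlon, dlat = local_offset_deg(base_lat, east, north)
        ids = np.array([f"A{k:08d}" for k in range(n_animal)])
        animal = _records(cities, city_idx, ids,
                          np.zeros(n_animal, dtype=int), [_ANIMAL_LABEL],
                          base_lon + dlon, base_lat + dlat)
        truth.animal_ids = ids.tolist()
        records = pd.concat([records, animal], ignore_index=True)

    return records.reset_index(drop=True), truth


def _records(cities, city_idx, ids, pick, labels, lon, lat) -> pd.DataFrame:
    majors = np.array([m for m, _ in labels])
    subs = np.array([s for _, s in labels])
    city = cities.iloc[city_idx]
    return pd.DataFrame({
        "id": ids,
        "name": np.char.add("Synthetic Facility ", ids.astype(str)),
        "major_category": majors[pick],
        "subcategory": subs[pick],
        "longitude": np.asarray(lon, float),
        "latitude": np.asarray(lat, float),
        "province_code": city["province_code"].to_numpy(),
        "province_name": city["province_name"].to_numpy(),
        "city_code": city["city_code"].to_numpy(),
        "city_name": city["city_name"].to_numpy(),
        "district_code": np.char.add(city["city_code"].to_numpy().astype(str), "01"),
        "district_name": np.char.add(city["city_name"].to_numpy().astype(str),
                                     " Central District"),
    })


def generate_gwr_surface(n_points: int, seed: int,
                         beta_fields: dict[str, object] | None = None,
                         noise_sd: float = 0.1) -> pd.DataFrame:
    """Planar test surface for locally weighted regression.

    Locations (u, v) are uniform on the unit square, the covariate x is
    standard normal, and y = beta0(u, v) + beta1(u, v) * x + eps with
    eps ~ Normal(0, noise_sd^2). True coefficient surfaces are returned in
    ``beta0_true`` / ``beta1_true`` for recovery testing.
    """
    if n_points < 10:
        raise ConfigurationError("n_points must be >= 10")
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be non-negative")
    beta_fields = beta_fields or {
        "beta0": lambda u, v: 1.0 + u + v,
        "beta1": lambda u, v: 1.0 + np.sin(np.pi * u) * np.cos(np.pi * v),
    }
    rng = np.random.default_rng(seed)
    u = rng.uniform(0.0, 1.0, n_points)
    v = rng.uniform(0.0, 1.0, n_points)
    x = rng.normal(0.0, 1.0, n_points)
    b0 = np.asarray(beta_fields["beta0"](u, v), dtype=float)
    b1 = np.asarray(beta_fields["beta1"](u, v), dtype=float)
    if not (np.all(np.isfinite(b0)) and np.all(np.isfinite(b1))):
        raise ConfigurationError("beta fields produced non-finite values")
    y = b0 + b1 * x + rng.normal(0.0, noise_sd, n_points)
    return pd.DataFrame({"u": u, "v": v, "x": x, "y": y,
                         "beta0_true": b0, "beta1_true": b1})


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    """Copy of ``config`` with a different root seed."""
    return replace(config, seed=seed)
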