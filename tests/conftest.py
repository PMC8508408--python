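"""Shared fixtures: printed-table fixtures and small synthetic datasets."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mrscore import synthetic
from mrscore.grading import LevelTally, level_shares
from mrscore.scoring import score_cities

# Six example rows of the national facility feed (as printed in the source
# dataset excerpt): mixed categories, three districts of Beijing.
TABLE1_CSV = """\
Id,Medical Institution Name,Hospital Major Category,Hospital Subcategory,Longitude,Latitude,Province Code,Province Name,City Code,City Name,District Code,District Name
B0FFG96ECS,Beida Yanyuan Clinic,Clinic,Clinic,116.23388,40.199571,110000,Beijing,10,Beijing,110114,Changping District
B0FFMBBJJJ,Shengwang Hearing Aids,Pharmacy,Pharmacy,116.233614,40.224711,110000,Beijing,10,Beijing,110114,Changping District
B0FFHTMPRN,Huanrong Dental Hospital,Specialized Hospital,Dental Hospital,116.233288,39.84639,110000,Beijing,10,Beijing,110106,Fengtai District
B0FFHN13UX,No. 2 Qingta Rural Hospital,General hospital,Rural hospital,116.253561,39.895062,110000,Beijing,10,Beijing,110106,Fengtai District
B0FFF0E9HD,Aiguo Hospital,Specialized Hospital,Dental Hospital,116.241367,40.207911,110000,Beijing,10,Beijing,110114,Changping District
B000A85U1D,Xishan Community Rural Hospital,General hospital,Rural hospital,116.238296,39.955099,110000,Beijing,10,Beijing,110108,Haidian District
"""


@pytest.fixture
def table1_path(tmp_path):
    path = tmp_path / "institutions.csv"
    path.write_text(TABLE1_CSV, encoding="utf-8")
    return path


@pytest.fixture(scope="session")
def small_config():
    return synthetic.SimulationConfig(
        n_provinces=4, cities_per_province=(3, 5), seed=11,
        pop_lognormal_mu_sigma=(13.0, 0.8))


@pytest.fixture(scope="session")
def small_dataset(small_config):
    cities = synthetic.generate_cities(small_config)
    records, truth = synthetic.generate_institutions(cities, small_config)
    return cities, records, truth


def scores_from_counts(seed: int):
    """Default-frame (369-unit) score table computed from sampled true
    counts, skipping point emission — used where only city scores matter."""
    cfg = synthetic.default_config(seed=seed)
    cities = synthetic.generate_cities(cfg)
    counts = synthetic.sample_level_counts(
        cities, cfg, np.random.default_rng([seed, 1]))
    totals = {lvl: int(counts[lvl].sum()) for lvl in (1, 2, 3)}
    tally = LevelTally(by_city=counts, totals=totals,
                       shares_pct=level_shares(totals))
    scores, refs = score_cities(tally, cities)
    return cities, scores


@pytest.fixture(scope="session")
def default_frame_scores():
    return scores_from_counts(seed=42)
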