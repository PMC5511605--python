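"""Shared fixtures: synthetic weather, environments and genotype panels.

Everything is generated programmatically at session start with fixed
seeds; no data files are stored.
"""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from optimet.cgm import DEFAULT_BOUNDS
from optimet.environments import (
    ClimateParams,
    Site,
    WeatherSeries,
    build_environments,
    concat_years,
    generate_synthetic_weather,
)
from optimet.genetics import assign_qtl, simulate_genotypes

SOWING_DATES = [
    dt.date(2001, 9, 15),
    dt.date(2001, 10, 15),
    dt.date(2001, 11, 15),
    dt.date(2002, 3, 15),
]


def _continuous_weather(sites, seed):
    series = generate_synthetic_weather(sites, 3, ClimateParams(), seed=seed, start_year=2001)
    by_site: dict[str, list] = {}
    for s in series:
        by_site.setdefault(s.site_id, []).append(s)
    return {sid: concat_years(lst) for sid, lst in by_site.items()}


@pytest.fixture(scope="session")
def const_env():
    """Constant 20 °C at the equator: day length exactly 12 h every day."""
    dates = pd.date_range("2001-01-01", periods=400)
    ws = WeatherSeries("eq", dates, np.full(400, 20.0))
    site = Site("eq", "equator bench", 0.0)
    return build_environments([site], [dt.date(2001, 1, 15)], {"eq": ws}, horizon_days=300)[0]


@pytest.fixture(scope="session")
def france_envs():
    """32 candidate environments: 8 sites across 43–50.5°N × 4 sowing dates."""
    sites = [Site(f"s{i}", f"site {i}", lat) for i, lat in enumerate(np.linspace(43.0, 50.5, 8))]
    weather = _continuous_weather(sites, seed=11)
    return build_environments(sites, SOWING_DATES, weather, horizon_days=300)


@pytest.fixture(scope="session")
def wide_envs():
    """32 candidate environments over a wider 40–56°N latitude gradient."""
    sites = [Site(f"s{i}", f"site {i}", lat) for i, lat in enumerate(np.linspace(40.0, 56.0, 8))]
    weather = _continuous_weather(sites, seed=11)
    return build_environments(sites, SOWING_DATES, weather, horizon_days=300)


@pytest.fixture(scope="session")
def qtl_truth_20():
    """20 inbred lines with QTL-architecture genetic parameter values."""
    genos = simulate_genotypes(20, n_chrom=7, markers_per_chrom=60, seed=0)
    arch, pruned = assign_qtl(genos, DEFAULT_BOUNDS, seed=0)
    return arch, pruned
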