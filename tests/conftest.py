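"""Shared fixtures: synthetic deployments and constructed dive profiles."""

import numpy as np
import pandas as pd
import pytest

import divetype as dt

#: canonical scenario seed used across the suite
SCENARIO_SEED = 42


def make_series(depth, tag_id="t1", start="2008-06-20T00:00:00Z", offset=-7.0):
    return dt.DepthSeries(tag_id=tag_id, start_time=pd.Timestamp(start),
                          depth=np.asarray(depth, dtype=float),
                          local_utc_offset=offset)


def trapezoid_dive(descent_s=400, bottom_s=600, ascent_s=400, depth=400.0,
                   lead_s=30, tail_s=30):
    """Surface, linear descent, flat bottom, linear ascent, surface."""
    parts = [
        np.zeros(lead_s),
        np.linspace(0.0, depth, descent_s + 1)[1:],
        np.full(bottom_s - 1, depth),
        np.linspace(depth, 0.0, ascent_s + 1)[1:],
        np.zeros(tail_s),
    ]
    return np.concatenate(parts)


@pytest.fixture(scope="session")
def small_deployment():
    """20 dives per type; quick enough for per-module tests."""
    cfg = dt.ScenarioConfig(n_dives_per_type=20, seed=SCENARIO_SEED)
    return dt.generate_deployment(cfg)


@pytest.fixture(scope="session")
def big_deployment():
    """The 1,200-dive (200 per type) recovery scenario."""
    cfg = dt.ScenarioConfig(n_dives_per_type=200, seed=SCENARIO_SEED)
    return dt.generate_deployment(cfg)


@pytest.fixture(scope="session")
def big_pipeline(big_deployment):
    dep = big_deployment
    return dt.run_pipeline(dep.series, dep.fixes, dep.grid)
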