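import numpy as np
import pandas as pd
import pytest

from ecoseasons import (
    GridSpec,
    RegimeSpec,
    SimConfig,
    make_landscape,
    prepare_daily_matrix,
    simulate_population,
)


def two_regime_spec():
    """The default two-season study population: a 3:1 step-scale ratio and
    distinct habitat preferences, switching at ordinal days 100 and 300."""
    return [
        RegimeSpec(
            "summer", start_day=100, end_day=299,
            step_scale=300.0, step_shape=2.0, angular_concentration=0.5,
            habitat_weights={"wetland": 1.5, "deciduous_forest": 0.8},
        ),
        RegimeSpec(
            "winter", start_day=300, end_day=99,
            step_scale=100.0, step_shape=2.0, angular_concentration=0.5,
            habitat_weights={"coniferous_forest": 1.5, "shrubland": 0.8},
        ),
    ]


def one_regime_spec():
    """A year-round single space-use regime (the null population)."""
    return [
        RegimeSpec(
            "allyear", start_day=1, end_day=365,
            step_scale=200.0, step_shape=2.0, angular_concentration=0.5,
            habitat_weights={"wetland": 1.0},
        )
    ]


@pytest.fixture(scope="session")
def mainland_landscape():
    return make_landscape(seed=1)


@pytest.fixture(scope="session")
def small_landscape():
    return make_landscape(seed=2, grid_spec=GridSpec(60, 60))


@pytest.fixture(scope="session")
def two_regime_population(mainland_landscape):
    cfg = SimConfig(regimes=two_regime_spec(), n_individuals=12, n_years=2, rng_seed=0)
    tracks, truth = simulate_population(mainland_landscape, cfg)
    return tracks, truth


@pytest.fixture(scope="session")
def two_regime_matrix(two_regime_population, mainland_landscape):
    tracks, _ = two_regime_population
    return prepare_daily_matrix(tracks, mainland_landscape)


def make_track(times_hours, xy=None, individual="a", start="2001-01-01"):
    """Build a minimal track frame from fix times in hours (and optional
    coordinates)."""
    t0 = pd.Timestamp(start, tz="UTC")
    ts = [t0 + pd.Timedelta(hours=float(h)) for h in times_hours]
    n = len(ts)
    if xy is None:
        xy = [(float(i) * 10.0, 0.0) for i in range(n)]
    return pd.DataFrame(
        {
            "individual_id": individual,
            "timestamp": ts,
            "x": [p[0] for p in xy],
            "y": [p[1] for p in xy],
        }
    )
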