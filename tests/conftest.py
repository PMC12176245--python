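"""Shared fixtures: one small simulated study reused across test modules."""

import warnings

import numpy as np
import pandas as pd
import pytest

from packmark import pipeline, synthetic
from packmark.pipeline import RunConfig
from packmark.synthetic import SimConfig
from packmark.territory import fit_ud, isopleth


@pytest.fixture(scope="session")
def sim_config() -> SimConfig:
    return SimConfig(seed=11)


@pytest.fixture(scope="session")
def layers(sim_config):
    return synthetic.simulate_landscape(sim_config)


@pytest.fixture(scope="session")
def fixes(sim_config):
    return synthetic.simulate_fixes(sim_config)


@pytest.fixture(scope="session")
def anchor(fixes):
    return pd.to_datetime(fixes["timestamp"]).max()


@pytest.fixture(scope="session")
def ud(fixes, anchor):
    return fit_ud(fixes, "pack_0", anchor, window_days=90)


@pytest.fixture(scope="session")
def territory_poly(ud):
    return isopleth(ud, 0.95)


@pytest.fixture(scope="session")
def territories(sim_config, fixes):
    return pipeline.build_territories(RunConfig(seed=sim_config.seed), fixes)


@pytest.fixture(scope="session")
def events(sim_config, layers, territories):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        terr = {p: territories[p]["territory"] for p in territories}
        return synthetic.simulate_follows(sim_config, layers, terr)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
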