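"""Shared fixtures.

The expensive artifacts — the full-design synthetic feature table and the
five-approach run on it — are built once per session at the 100 MHz
simulation rate and a fixed seed, and reused by the experiment and
acceptance tests.
"""

import numpy as np
import pytest

from sonoyeast.experiments import RunConfig, build_feature_table, run_all
from sonoyeast.simulate import AcousticParams, SimConfig, VesselGeometry

SESSION_SEED = 1


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def params():
    return AcousticParams()

@pytest.fixture
def quiet_params():
    return AcousticParams(noise_std=0.0, count_cv=0.0)


@pytest.fixture
def geometry():
    return VesselGeometry()


@pytest.fixture
def sim_config():
    return SimConfig(sampling_rate=1e8)


@pytest.fixture(scope="session")
def run_config():
    return RunConfig()


@pytest.fixture(scope="session")
def feature_rows(run_config):
    return build_feature_table(run_config, SESSION_SEED)


@pytest.fixture(scope="session")
def full_run(run_config, feature_rows):
    """Report and models of a complete five-approach run on the shared table."""
    return run_all(run_config, SESSION_SEED, rows=feature_rows)
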