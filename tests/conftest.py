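import numpy as np
import pytest

from phenoflight.simdata import SimConfig, simulate

SHARES_SMALL = {
    "NGRDI": {"flight": 0.60, "rep_in_flight": 0.10,
              "genotype_in_flight": 0.15, "residual": 0.15},
    "CHM": {"flight": 0.90, "rep_in_flight": 0.02,
            "genotype_in_flight": 0.04, "residual": 0.04},
}


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(n_parents=12, n_hybrids=30, n_markers=200,
                     n_flights_rgb=6, seed=42, variance_shares=SHARES_SMALL)


@pytest.fixture(scope="session")
def small_trial(small_config):
    return simulate(small_config)


@pytest.fixture(scope="session")
def om_table(small_trial):
    return small_trial.phenomic[small_trial.phenomic.trial == "OM"]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
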