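"""Shared fixtures: one small seeded simulation reused across test modules."""

import pytest

from epicascade.synthetic import (SimulationConfig, simulate_cohort,
                                  simulate_ko_experiment,
                                  simulate_methylight_plate,
                                  simulate_prior_list)


@pytest.fixture(scope="session")
def sim_config():
    return SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def ko_experiment(sim_config):
    return simulate_ko_experiment(sim_config)


@pytest.fixture(scope="session")
def cohort(sim_config, ko_experiment):
    truth = ko_experiment[3]
    return simulate_cohort(sim_config, truth)


@pytest.fixture(scope="session")
def prior_list(sim_config, ko_experiment):
    return simulate_prior_list(sim_config, ko_experiment[3])


@pytest.fixture(scope="session")
def ct_table(sim_config):
    return simulate_methylight_plate(sim_config)
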