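"""Shared fixtures: one session-scoped synthetic experiment plus derived
normalization and thresholds, so expensive generation happens once."""

import numpy as np
import pytest

from citegate import (
    SimConfig,
    build_threshold_table,
    normalize_experiment,
    simulate_experiment,
)


@pytest.fixture(scope="session")
def sim_default():
    """Default-design experiment at desk scale: 60 subjects x 40 cells."""
    config = SimConfig(rng_seed=11, n_cells_per_subject=40)
    experiment, truth = simulate_experiment(config)
    return config, experiment, truth


@pytest.fixture(scope="session")
def experiment(sim_default):
    return sim_default[1]


@pytest.fixture(scope="session")
def truth(sim_default):
    return sim_default[2]


@pytest.fixture(scope="session")
def normalized(experiment):
    return normalize_experiment(experiment.rna, experiment.adt)


@pytest.fixture(scope="session")
def threshold_table(normalized, experiment):
    return build_threshold_table(normalized, experiment.antibody_names)


@pytest.fixture(scope="session")
def singlet_mask(truth):
    return ~truth.is_doublet


@pytest.fixture(scope="session")
def true_threshold_vector(experiment, truth):
    return np.array([truth.true_thresholds[a] for a in experiment.antibody_names])
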