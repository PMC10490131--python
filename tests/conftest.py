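"""Shared fixtures: parameter boxes, reference sets, and a small trained net."""

from __future__ import annotations

import numpy as np
import pytest

from rheoinverse import (
    NetConfig,
    TrainingConfig,
    default_bounds,
    generate_dataset,
    load_lambda_dna_params,
    log_rate_grid,
    train,
)


@pytest.fixture(scope="session")
def bounds():
    """The default admissible parameter box for entangled solutions."""
    return default_bounds()


@pytest.fixture(scope="session")
def dna_sets():
    """(concentration, params) reference sets for the lambda-DNA solutions."""
    return load_lambda_dna_params()


@pytest.fixture(scope="session")
def rates91():
    return log_rate_grid()


@pytest.fixture(scope="session")
def small_dataset(bounds):
    """A quick 200-set x 7-rate dataset for surrogate mechanics tests."""
    return generate_dataset(bounds, 200, np.logspace(-4, 4, 7), seed=1234, split=(10, 3, 2))


@pytest.fixture(scope="session")
def small_net(small_dataset):
    """A modest net trained briefly: functional, not accurate."""
    net, _ = train(
        NetConfig(n_hidden_layers=2, neurons_per_layer=32),
        small_dataset,
        TrainingConfig(n_epochs=60, batch_size=256, seed=5, n_repeats=1, patience=60),
    )
    return net
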