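"""Shared fixtures: small simulated ensembles, reused across modules."""

import numpy as np
import pytest

import e2afiber as ef


@pytest.fixture(scope="session")
def params_regular():
    return ef.default_params().regular()


@pytest.fixture(scope="session")
def params_depleted():
    return ef.default_params()


@pytest.fixture(scope="session")
def small_regular_ensemble(params_regular):
    """8 regular fibers of 40 kbp: quick, enough statistics for shapes."""
    cfg = ef.SimulationConfig(
        params=params_regular, fiber_length_bp=40_000, n_fibers=8, rng_seed=101
    )
    return ef.simulate_ensemble(cfg)


@pytest.fixture(scope="session")
def small_depleted_ensemble(params_depleted):
    cfg = ef.SimulationConfig(
        params=params_depleted, fiber_length_bp=40_000, n_fibers=8, rng_seed=101
    )
    return ef.simulate_ensemble(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
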