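"""Shared fixtures: a small synthetic domain, surrogate and fitted
emulators reused across the unit-test modules (GP fits are the expensive
part, so they are session-scoped)."""

import numpy as np
import pytest

from aqemu import design, emulation, synthetic

DOMAIN_SEED = 1
SIM_SEED = 2
DESIGN_SEEDS = (3, 4)
FIT_SEED = 5


@pytest.fixture(scope="session")
def domain():
    return synthetic.make_domain(n_cells=40, n_prefectures=8, seed=DOMAIN_SEED)


@pytest.fixture(scope="session")
def simulator(domain):
    return synthetic.make_simulator(domain, seed=SIM_SEED)


@pytest.fixture(scope="session")
def linear_simulator(domain):
    """Exactly linear PM response (power exponents pinned to 1)."""
    return synthetic.make_simulator(domain, seed=SIM_SEED, pm_nonlinearity=0.0)


@pytest.fixture(scope="session")
def designs():
    return design.train_test_designs(n_train=30, n_test=5, seeds=DESIGN_SEEDS)


@pytest.fixture(scope="session")
def baseline_rates():
    return synthetic.make_baseline_rates(seed=7)


@pytest.fixture(scope="session")
def small_emulator_set(simulator, designs):
    """PM and O3 emulators for the first 8 cells of the small domain."""
    train, _ = designs
    pm, o3 = synthetic.simulate_many(simulator, train.X)
    fields = {"PM2.5": pm.T[:, :8], "O3": o3.T[:, :8]}
    return emulation.fit_all(train.X, fields, seed=FIT_SEED)
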