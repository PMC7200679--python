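import numpy as np
import pytest

from dyadsync import SimulationConfig, build_synchrony_table, simulate_study


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_study():
    """Six dyads, both conditions, clear coupling contrast (shared across tests)."""
    cfg = SimulationConfig(n_dyads=6, coupling_tog=0.8, coupling_sep=0.1, seed=7)
    sessions, covariates, truth = simulate_study(cfg)
    return sessions, covariates, truth


@pytest.fixture(scope="session")
def small_table(small_study):
    sessions, _, _ = small_study
    return build_synchrony_table(sessions, n_control=1, control_seed=11)
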