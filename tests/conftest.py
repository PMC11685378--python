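import numpy as np
import pytest

from plexcore import planted_core_multiplex, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """35-subject cohort on 40 nodes; heavy enough to exercise every stage."""
    data, truth = simulate_cohort(
        n_hc=15, n_ms=20, n_nodes=40, n_core=8, seed=1234
    )
    return data, truth


@pytest.fixture(scope="session")
def strong_planted_multiplex():
    """114-node multiplex with a 20-node planted core at strong signal."""
    mx, core = planted_core_multiplex(
        114, range(20), weight_means=(1.0, 0.4, 0.1), noise=0.3, seed=7
    )
    return mx, core


@pytest.fixture
def rng():
    return np.random.default_rng(0)
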