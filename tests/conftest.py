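import numpy as np
import pytest

from wmnet.atlas import attach_wholebrain_indices, build_wm_node_set, load_default_lookup
from wmnet.simulate import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def hierarchy():
    return build_wm_node_set()


@pytest.fixture(scope="session")
def hierarchy_wb():
    return attach_wholebrain_indices(build_wm_node_set(), load_default_lookup())


@pytest.fixture(scope="session")
def small_cohort(hierarchy_wb):
    """A 12-per-group null cohort, reused across tests."""
    cfg = SimConfig(n_per_group=12, seed=7)
    return cfg, generate_cohort(cfg, hierarchy_wb)


def random_graph(rng: np.random.Generator, n: int, density: float = 0.7,
                 connected: bool = True) -> np.ndarray:
    """Random symmetric nonnegative loop-free weight matrix."""
    w = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    vals = rng.gamma(2.0, 1.0, size=len(iu[0]))
    vals *= rng.random(len(vals)) < density
    w[iu] = vals
    w = w + w.T
    if connected:
        # weak ring guarantees a single component
        for i in range(n):
            j = (i + 1) % n
            if w[i, j] == 0:
                w[i, j] = w[j, i] = 0.05
    return w
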