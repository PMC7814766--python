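import numpy as np
import pytest

from scnet.covariance import BinaryGraph
from scnet.synthetic import SyntheticConfig, generate_cohort


def graph_from(adjacency) -> BinaryGraph:
    a = np.asarray(adjacency, dtype=np.int8)
    return BinaryGraph(a, density=a.sum() / max(a.shape[0] * (a.shape[0] - 1), 1))


@pytest.fixture(scope="session")
def k4():
    return graph_from(1 - np.eye(4, dtype=int))


@pytest.fixture(scope="session")
def p3():
    return graph_from([[0, 1, 0], [1, 0, 1], [0, 1, 0]])


@pytest.fixture(scope="session")
def star4():
    """Star K1,3 with the hub at node 0."""
    a = np.zeros((4, 4), dtype=int)
    a[0, 1:] = a[1:, 0] = 1
    return graph_from(a)


@pytest.fixture(scope="session")
def small_cohort():
    """Two-site, two-group cohort with planted 4-block covariance (fast)."""
    config = SyntheticConfig(
        n_regions=20,
        module_labels=np.repeat([1, 2, 3, 4], 5),
        per_site_counts={"site01": 25, "site02": 25},
        rho_within=0.6,
        rho_between=0.1,
        site_scales={"site01": 1.0, "site02": 2.0},
        seed=7,
    )
    return config, generate_cohort(config)
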