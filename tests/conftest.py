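import numpy as np
import pytest

from netbackbone.graph import WeightedNetwork
from netbackbone.synth import fixture, gen_heterogeneous


@pytest.fixture
def triangle():
    return fixture("triangle_unit")


@pytest.fixture
def path3():
    return fixture("path3_unit")


@pytest.fixture
def star5():
    return fixture("star5_geometric")


@pytest.fixture
def two_cliques():
    return fixture("two_cliques")


@pytest.fixture
def gloss30():
    return fixture("conditional_gloss_30")


@pytest.fixture(scope="session")
def het100():
    """Medium heterogeneous network (integer weights, single component)."""
    return gen_heterogeneous(n=100, mean_degree=6.0, seed=0)


@pytest.fixture(scope="session")
def ecm_net20():
    """Small network whose degree/strength sequence the ECM can fit."""
    return gen_heterogeneous(
        n=20, mean_degree=4.0, weight_model="poisson_shifted", seed=7
    )


def random_network(seed: int, n: int = 12, p: float = 0.35) -> WeightedNetwork:
    """Seeded Erdős–Rényi-style weighted network for property tests."""
    rng = np.random.default_rng(seed)
    while True:
        edges = []
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < p:
                    edges.append((f"n{i}", f"n{j}", int(rng.integers(1, 30))))
        if edges:
            return WeightedNetwork.from_edges(edges, name=f"rand-{seed}")
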