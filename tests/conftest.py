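import pytest

from spnet import datasets


@pytest.fixture(scope="session")
def cluster_net():
    return datasets.cluster_demo()


@pytest.fixture(scope="session")
def connect_net():
    return datasets.connect_demo()


@pytest.fixture(scope="session")
def directed_net():
    return datasets.directed_demo()


def seeded_instances(count, base_seed, n_range=(4, 10)):
    """A deterministic sweep of random-graph study conditions.

    Cycles through directed/undirected x unweighted/positive-weighted,
    with n and edge probability varying over the sweep.
    """
    lo, hi = n_range
    out = []
    for i in range(count):
        n = lo + i % (hi - lo + 1)
        p = (0.2, 0.3, 0.4)[i % 3]
        directed = (i // 2) % 2 == 1
        weighted = i % 2 == 1
        g = datasets.random_graph(
            n,
            p,
            directed=directed,
            weighted=weighted,
            weight_range=(0.5, 2.0),
            seed=base_seed + i,
        )
        out.append(g)
    return out
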