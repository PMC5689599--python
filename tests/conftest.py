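import networkx as nx
import numpy as np
import pytest


def er_network(n: int, p: float, seed: int) -> nx.Graph:
    """Random gene network with symbol-named nodes."""
    g = nx.gnp_random_graph(n, p, seed=seed)
    return nx.relabel_nodes(g, {i: f"G{i:03d}" for i in g.nodes()})


@pytest.fixture
def path_net() -> nx.Graph:
    net = nx.Graph()
    net.add_edges_from([("A", "B"), ("B", "C")])
    return net


@pytest.fixture
def star_net() -> nx.Graph:
    net = nx.Graph()
    net.add_edges_from([("HUB", leaf) for leaf in ("L1", "L2", "L3", "L4", "L5")])
    return net


@pytest.fixture(scope="session")
def small_benchmark():
    """A compact planted benchmark shared by the slower integration tests."""
    from obnet.synthetic import FixtureSpec, generate_benchmark

    spec = FixtureSpec(
        n_genes=400,
        n_modules=4,
        module_size_range=(40, 60),
        n_diseases=8,
        n_planted_ord=3,
        n_obesity_genes=25,
        n_disease_genes=40,
        seed=5,
    )
    return generate_benchmark(spec)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
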