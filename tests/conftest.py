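import networkx as nx
import numpy as np
import pytest

from osdis import Network, assign_delays


def make_weighted(edges):
    """Network from (u, v, delay) triples."""
    g = nx.Graph()
    for u, v, th in edges:
        g.add_edge(u, v, delay=th)
    return Network(g)


@pytest.fixture
def path_net():
    """Path 0-1-2 with delays 3, 2."""
    return make_weighted([(0, 1, 3.0), (1, 2, 2.0)])


@pytest.fixture
def star_net():
    """Star with centre 0 and spokes 1..4, delays 1..4."""
    return make_weighted([(0, i, float(i)) for i in range(1, 5)])


def random_connected_net(n, p, seed, with_delays=True):
    """Erdos-Renyi graph conditioned on connectivity, optional delays."""
    rng = np.random.default_rng(seed)
    for attempt in range(200):
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        if nx.is_connected(g):
            net = Network(g)
            if with_delays:
                net = assign_delays(net, seed=int(rng.integers(2**31)))
            return net
    raise RuntimeError("could not draw a connected graph")


def random_tree_net(n, seed):
    """Uniform random labeled tree with Gaussian delays."""
    g = nx.random_labeled_tree(n, seed=seed)
    return assign_delays(Network(g), seed=seed)
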