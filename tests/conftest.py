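import numpy as np
import pytest

from fcnet.connectivity import BinaryGraph


def adjacency_from_edges(n, edges):
    adj = np.zeros((n, n), dtype=np.uint8)
    for i, j in edges:
        adj[i, j] = adj[j, i] = 1
    return adj


def graph_from_edges(n, edges, sparsity=0.0):
    return BinaryGraph(adjacency=adjacency_from_edges(n, edges),
                       sparsity=sparsity)


def random_graph(rng, n, p=None, m=None):
    """Erdos-Renyi-like graph: G(n, p) or G(n, m) with uniform edges."""
    iu = np.triu_indices(n, 1)
    n_pairs = len(iu[0])
    if m is not None:
        keep = rng.choice(n_pairs, size=m, replace=False)
        mask = np.zeros(n_pairs, dtype=bool)
        mask[keep] = True
    else:
        mask = rng.random(n_pairs) < p
    adj = np.zeros((n, n), dtype=np.uint8)
    adj[iu[0][mask], iu[1][mask]] = 1
    adj += adj.T
    return BinaryGraph(adjacency=adj)


@pytest.fixture
def k4():
    """Complete graph on 4 nodes."""
    return graph_from_edges(4, [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3),
                                (2, 3)])


@pytest.fixture
def star3():
    """Star: center 0 with 3 leaves."""
    return graph_from_edges(4, [(0, 1), (0, 2), (0, 3)])


@pytest.fixture
def path4():
    """Path a-b-c-d."""
    return graph_from_edges(4, [(0, 1), (1, 2), (2, 3)])


@pytest.fixture
def two_triangles():
    """Two disjoint triangles."""
    return graph_from_edges(6, [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5),
                                (3, 5)])


@pytest.fixture
def ring_lattice_20_4():
    """Ring lattice, N=20, each node linked to its 4 nearest neighbors."""
    n, k = 20, 4
    edges = [(i, (i + d) % n) for i in range(n) for d in (1, 2)]
    edges = [(min(a, b), max(a, b)) for a, b in edges]
    return graph_from_edges(n, edges)
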