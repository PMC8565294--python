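"""Compiled inner loops for binary-graph metrics.

All kernels operate on dense uint8 adjacency matrices (symmetric, zero
diagonal).  They are deliberately allocation-light so that large metric
sweeps (many subjects x many sparsity points x many null graphs) stay
cheap on a single core.
"""

import numpy as np
from numba import njit

__all__ = [
    "pairwise_distances",
    "local_efficiency_nodal",
    "betweenness_nodal",
    "double_edge_swap",
]


@njit(cache=True)
def pairwise_distances(adj):
    """All-pairs unweighted shortest-path lengths by BFS from every node.

    Unreachable pairs are left at +inf; the diagonal is 0.
    """
    n = adj.shape[0]
    dist = np.full((n, n), np.inf)
    queue = np.empty(n, np.int64)
    for s in range(n):
        dist[s, s] = 0.0
        head = 0
        tail = 0
        queue[tail] = s
        tail += 1
        while head < tail:
            u = queue[head]
            head += 1
            du = dist[s, u]
            for v in range(n):
                if adj[u, v] != 0 and dist[s, v] == np.inf:
                    dist[s, v] = du + 1.0
                    queue[tail] = v
                    tail += 1
    return dist


@njit(cache=True)
def _efficiency_sum(dist):
    n = dist.shape[0]
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and dist[i, j] != np.inf:
                total += 1.0 / dist[i, j]
    return total


@njit(cache=True)
def local_efficiency_nodal(adj):
    """Nodal local efficiency: global efficiency of each node's
    neighbor-induced subgraph (the node itself excluded).

    Nodes of degree < 2 get 0.
    """
    n = adj.shape[0]
    out = np.zeros(n)
    neigh = np.empty(n, np.int64)
    for i in range(n):
        k = 0
        for j in range(n):
            if adj[i, j] != 0:
                neigh[k] = j
                k += 1
        if k < 2:
            continue
        sub = np.empty((k, k), np.uint8)
        for a in range(k):
            for b in range(k):
                sub[a, b] = adj[neigh[a], neigh[b]]
        d = pairwise_distances(sub)
        out[i] = _efficiency_sum(d) / (k * (k - 1))
    return out


@njit(cache=True)
def betweenness_nodal(adj):
    """Betweenness centrality by Brandes' dependency accumulation.

    Returns, per node, the sum over unordered source-target pairs of the
    fraction of shortest paths passing through the node (raw pair counts,
    not normalized).  Predecessors are recovered from the BFS level
    structure instead of stored lists, trading O(N) neighbor scans for
    zero per-source allocation of path lists.
    """
    n = adj.shape[0]
    bc = np.zeros(n)
    sigma = np.zeros(n)
    dist = np.empty(n, np.int64)
    delta = np.zeros(n)
    order = np.empty(n, np.int64)
    for s in range(n):
        for i in range(n):
            sigma[i] = 0.0
            dist[i] = -1
            delta[i] = 0.0
        sigma[s] = 1.0
        dist[s] = 0
        head = 0
        tail = 0
        order[tail] = s
        tail += 1
        while head < tail:
            u = order[head]
            head += 1
            for v in range(n):
                if adj[u, v] != 0:
                    if dist[v] < 0:
                        dist[v] = dist[u] + 1
                        order[tail] = v
                        tail += 1
                    if dist[v] == dist[u] + 1:
                        sigma[v] += sigma[u]
        for idx in range(tail - 1, -1, -1):
            w = order[idx]
            for v in range(n):
                if adj[v, w] != 0 and dist[v] == dist[w] - 1:
                    delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
    return bc / 2.0


@njit(cache=True)
def double_edge_swap(adj, edges, pick, orient):
    """Degree-preserving rewiring by Maslov-Sneppen double-edge swaps.

    `adj` and `edges` (E x 2) are modified in place.  One attempt per row
    of `pick` (two edge indices in [0, E)); `orient` holds one random bit
    per attempt selecting the endpoint pairing, which removes the
    orientation bias of always rewiring stored-order endpoints.  An
    attempt is discarded when the two edges share a node or when either
    replacement edge already exists.  Returns the number of successful
    swaps.
    """
    n_attempts = pick.shape[0]
    swapped = 0
    for t in range(n_attempts):
        e1 = pick[t, 0]
        e2 = pick[t, 1]
        if e1 == e2:
            continue
        a = edges[e1, 0]
        b = edges[e1, 1]
        if orient[t] != 0:
            a, b = b, a
        c = edges[e2, 0]
        d = edges[e2, 1]
        if a == c or a == d or b == c or b == d:
            continue
        # rewire (a,b),(c,d) -> (a,d),(c,b)
        if adj[a, d] != 0 or adj[c, b] != 0:
            continue
        adj[a, b] = 0
        adj[b, a] = 0
        adj[c, d] = 0
        adj[d, c] = 0
        adj[a, d] = 1
        adj[d, a] = 1
        adj[c, b] = 1
        adj[b, c] = 1
        edges[e1, 0] = a
        edges[e1, 1] = d
        edges[e2, 0] = c
        edges[e2, 1] = b
        swapped += 1
    return swapped
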