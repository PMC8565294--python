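"""Independent brute-force reference implementations for small graphs.

Deliberately naive (Floyd-Warshall distances, exhaustive triangle
counting, explicit shortest-path enumeration for betweenness) so they
share no code path with the package's fast implementations.
"""

import numpy as np


def floyd_warshall(adj):
    n = len(adj)
    d = np.full((n, n), np.inf)
    for i in range(n):
        d[i, i] = 0.0
    for i in range(n):
        for j in range(n):
            if adj[i][j]:
                d[i, j] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def clustering(adj):
    n = len(adj)
    cs = np.zeros(n)
    for i in range(n):
        neigh = [j for j in range(n) if adj[i][j]]
        k = len(neigh)
        if k < 2:
            continue
        links = sum(1 for a in range(k) for b in range(a + 1, k)
                    if adj[neigh[a]][neigh[b]])
        cs[i] = 2.0 * links / (k * (k - 1))
    return cs, float(cs.mean())


def char_path_length(adj):
    d = floyd_warshall(adj)
    n = len(adj)
    vals = [d[i, j] for i in range(n) for j in range(n)
            if i != j and np.isfinite(d[i, j])]
    disconnected = any(not np.isfinite(d[i, j]) for i in range(n)
                       for j in range(n) if i != j)
    return float(np.mean(vals)), disconnected


def global_efficiency(adj):
    d = floyd_warshall(adj)
    n = len(adj)
    total = sum(1.0 / d[i, j] for i in range(n) for j in range(n)
                if i != j and np.isfinite(d[i, j]))
    return total / (n * (n - 1))


def nodal_efficiency(adj):
    d = floyd_warshall(adj)
    n = len(adj)
    out = np.zeros(n)
    for i in range(n):
        out[i] = sum(1.0 / d[i, j] for j in range(n)
                     if j != i and np.isfinite(d[i, j])) / (n - 1)
    return out


def local_efficiency(adj):
    n = len(adj)
    out = np.zeros(n)
    for i in range(n):
        neigh = [j for j in range(n) if adj[i][j]]
        if len(neigh) < 2:
            continue
        sub = [[adj[a][b] for b in neigh] for a in neigh]
        out[i] = global_efficiency(sub)
    return out, float(out.mean())


def _all_shortest_paths(adj, d, s, t):
    """Enumerate every shortest s-t path as a node list."""
    if not np.isfinite(d[s, t]):
        return []
    n = len(adj)
    paths = []

    def extend(path):
        u = path[-1]
        if u == t:
            paths.append(list(path))
            return
        for v in range(n):
            if adj[u][v] and d[s, v] == d[s, u] + 1 \
                    and d[v, t] == d[u, t] - 1:
                path.append(v)
                extend(path)
                path.pop()

    extend([s])
    return paths


def betweenness(adj):
    """Betweenness by full shortest-path enumeration (unordered pairs)."""
    n = len(adj)
    d = floyd_warshall(adj)
    bc = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            paths = _all_shortest_paths(adj, d, s, t)
            if not paths:
                continue
            for path in paths:
                for v in path[1:-1]:
                    bc[v] += 1.0 / len(paths)
    return bc


def degrees(adj):
    return np.array([sum(row) for row in adj])
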