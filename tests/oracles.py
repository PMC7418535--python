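"""Independent brute-force oracles for graph quantities.

Everything here works directly on small dense adjacency matrices by
exhaustive enumeration (triangles, path enumeration, set partitions,
label permutations) and is deliberately independent of the package
implementation and of networkx.
"""

import itertools

import numpy as np


def floyd_warshall(adj):
    n = adj.shape[0]
    dist = np.where(adj > 0, 1.0, np.inf)
    np.fill_diagonal(dist, 0.0)
    for k in range(n):
        dist = np.minimum(dist, dist[:, [k]] + dist[[k], :])
    return dist


def bf_clustering(adj):
    """Mean triangle fraction around nodes (0 for degree < 2)."""
    n = adj.shape[0]
    total = 0.0
    for i in range(n):
        nbrs = np.flatnonzero(adj[i])
        k = len(nbrs)
        if k < 2:
            continue
        links = sum(adj[u, v] for u, v in itertools.combinations(nbrs, 2))
        total += 2.0 * links / (k * (k - 1))
    return total / n


def bf_global_efficiency(adj):
    dist = floyd_warshall(adj)
    n = adj.shape[0]
    inv = np.where((dist > 0) & np.isfinite(dist), 1.0 / dist, 0.0)
    return inv.sum() / (n * (n - 1))


def bf_path_length(adj):
    dist = floyd_warshall(adj)
    finite = dist[(dist > 0) & np.isfinite(dist)]
    return finite.mean()


def _all_shortest_paths(adj, s, t):
    """Enumerate every shortest s-t path by breadth-limited DFS."""
    dist = floyd_warshall(adj)
    if not np.isfinite(dist[s, t]):
        return []
    target = dist[s, t]
    paths = []

    def extend(path):
        u = path[-1]
        if u == t:
            paths.append(list(path))
            return
        for v in np.flatnonzero(adj[u]):
            if dist[s, v] == len(path) and dist[v, t] == target - len(path):
                extend(path + [v])

    extend([s])
    return paths


def bf_betweenness(adj):
    """Normalized fractional betweenness by full path enumeration."""
    n = adj.shape[0]
    score = np.zeros(n)
    for s, t in itertools.combinations(range(n), 2):
        paths = _all_shortest_paths(adj, s, t)
        if not paths:
            continue
        for path in paths:
            for v in path[1:-1]:
                score[v] += 1.0 / len(paths)
    return score / ((n - 1) * (n - 2) / 2.0)


def bf_closeness(adj):
    """1 / mean distance to reachable nodes (connected graphs)."""
    dist = floyd_warshall(adj)
    n = adj.shape[0]
    out = np.zeros(n)
    for i in range(n):
        d = [dist[i, j] for j in range(n) if j != i and np.isfinite(dist[i, j])]
        out[i] = len(d) / sum(d) if d else 0.0
    return out


def bf_modularity(adj, labels):
    """Newman-Girvan Q from the definition: sum over node pairs of
    (A_ij - k_i k_j / 2m) * delta(c_i, c_j) / 2m."""
    k = adj.sum(axis=0)
    m2 = adj.sum()  # = 2m
    labels = np.asarray(labels)
    q = 0.0
    n = adj.shape[0]
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                q += adj[i, j] - k[i] * k[j] / m2
    return q / m2


def set_partitions(items):
    """All set partitions of a list (Bell-number many)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in set_partitions(rest):
        for i in range(len(smaller)):
            yield smaller[:i] + [[first] + smaller[i]] + smaller[i + 1:]
        yield [[first]] + smaller


def bf_best_modularity(adj):
    """Maximum Q over every possible partition (<= 8 nodes)."""
    n = adj.shape[0]
    best = -np.inf
    for parts in set_partitions(range(n)):
        labels = np.empty(n, dtype=int)
        for c, block in enumerate(parts):
            labels[block] = c
        best = max(best, bf_modularity(adj, labels))
    return best


def bf_participation(adj, labels):
    labels = np.asarray(labels)
    n = adj.shape[0]
    out = np.zeros(n)
    for i in range(n):
        k = adj[i].sum()
        if k == 0:
            continue
        out[i] = 1.0 - sum((adj[i, labels == c].sum() / k) ** 2
                           for c in np.unique(labels))
    return out


def bf_zrand(labels_a, labels_b):
    """z-rand by exhaustive enumeration of all node-label permutations."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    n = len(a)
    triu = np.triu_indices(n, 1)
    same_a = (a[:, None] == a[None, :])[triu]

    def w_of(bb):
        return int((same_a & (bb[:, None] == bb[None, :])[triu]).sum())

    ws = np.array([w_of(b[list(p)]) for p in itertools.permutations(range(n))],
                  dtype=float)
    return (w_of(b) - ws.mean()) / ws.std()


def random_connected_graph(rng, n, p=0.5):
    """Random connected adjacency matrix (rejection sampling)."""
    while True:
        upper = rng.random((n, n)) < p
        adj = np.triu(upper, 1)
        adj = (adj + adj.T).astype(int)
        if np.isfinite(floyd_warshall(adj)).all() and adj.sum() >= 2:
            return adj
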