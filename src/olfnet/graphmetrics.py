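"""Graph-theoretic characterization of binary and weighted networks.

Implements every meso-scale quantity the analysis reports: clustering
coefficient and global efficiency (binary and weighted), characteristic
path length, the three node centralities (degree, betweenness,
closeness) with composite hub scores, participation coefficient, Louvain
and Girvan-Newman modularity with permutation null z-scores, the
small-world index sigma against degree-preserving rewiring nulls, node
deletion resilience, and the standardized pair-counting Rand similarity
(z-rand) between partitions.

Conventions follow the standard brain-connectivity toolbox forms:
weighted clustering uses the geometric mean of triangle weights
(weights normalized by the network maximum), weighted path lengths use
edge length = 1/weight, betweenness counts shortest-path multiplicity
fractionally, and "random reassignment of connections" means
degree-preserving (Maslov-Sneppen) rewiring unless an Erdos-Renyi null
is requested.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .containers import BinaryNetwork, Partition

log = logging.getLogger(__name__)


def _as_graph(net) -> nx.Graph:
    if isinstance(net, BinaryNetwork):
        return net.to_networkx()
    if isinstance(net, nx.Graph):
        return net
    raise TypeError(f"expected BinaryNetwork or networkx Graph, got {type(net)}")


def _check_weights(g: nx.Graph, weighted: bool) -> None:
    if weighted:
        for _, _, w in g.edges(data="weight", default=1.0):
            if w < 0:
                raise ValueError("negative edge weights are not supported")


# ---------------------------------------------------------------------------
# Global metrics
# ---------------------------------------------------------------------------

def clustering_coefficient(net, weighted: bool = False) -> float:
    """Mean local clustering. Binary: fraction of closed triangles around
    each node; weighted: geometric-mean-of-triangle-weights (Onnela)
    form. Isolated and degree-1 nodes contribute 0."""
    g = _as_graph(net)
    if g.number_of_nodes() < 3:
        raise ValueError("clustering needs >= 3 nodes")
    _check_weights(g, weighted)
    return float(nx.average_clustering(g, weight="weight" if weighted else None))


def _length_attr(g: nx.Graph, weighted: bool) -> str | None:
    if not weighted:
        return None
    for u, v, w in g.edges(data="weight", default=1.0):
        g[u][v]["length"] = 1.0 / w if w > 0 else math.inf
    return "length"


def global_efficiency(net, weighted: bool = False) -> float:
    """Mean over ordered node pairs of 1/shortest-path-length;
    disconnected pairs contribute 0. Weighted paths use edge length
    1/weight."""
    g = _as_graph(net)
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError("global efficiency needs >= 2 nodes")
    _check_weights(g, weighted)
    attr = _length_attr(g, weighted)
    if attr is None:
        lengths = nx.all_pairs_shortest_path_length(g)
    else:
        lengths = nx.all_pairs_dijkstra_path_length(g, weight=attr)
    total = 0.0
    for _, dist in lengths:
        total += sum(1.0 / d for d in dist.values() if d > 0)
    return total / (n * (n - 1))


def characteristic_path_length(net, weighted: bool = False,
                               connected_pairs_only: bool = True) -> float:
    """Mean shortest-path length over node pairs. With
    ``connected_pairs_only`` (default) disconnected pairs are skipped,
    which keeps the quantity defined on rewired null draws that happen
    to disconnect."""
    g = _as_graph(net)
    if g.number_of_nodes() < 2:
        raise ValueError("path length needs >= 2 nodes")
    _check_weights(g, weighted)
    attr = _length_attr(g, weighted)
    if attr is None:
        lengths = nx.all_pairs_shortest_path_length(g)
    else:
        lengths = nx.all_pairs_dijkstra_path_length(g, weight=attr)
    total, count = 0.0, 0
    n = g.number_of_nodes()
    for _, dist in lengths:
        finite = [d for d in dist.values() if d > 0]
        total += sum(finite)
        count += len(finite)
    if not connected_pairs_only and count < n * (n - 1):
        raise ValueError("graph is disconnected: path length undefined")
    if count == 0:
        raise ValueError("no connected pairs: path length undefined")
    return total / count


# ---------------------------------------------------------------------------
# Centralities, hubs, participation
# ---------------------------------------------------------------------------

def centralities(net) -> pd.DataFrame:
    """Per-node degree, betweenness (fraction of shortest paths through
    the node, endpoints excluded, Brandes multiplicity convention) and
    closeness (reciprocal of the mean path length to all other nodes;
    computed per reachable set with a warning if disconnected)."""
    g = _as_graph(net)
    if g.number_of_nodes() < 2:
        raise ValueError("centralities need >= 2 nodes")
    if not nx.is_connected(g):
        warnings.warn("graph is disconnected: closeness computed per "
                      "reachable set")
    deg = dict(g.degree())
    btw = nx.betweenness_centrality(g, normalized=True)
    clo = nx.closeness_centrality(g, wf_improved=False)
    nodes = list(g.nodes())
    return pd.DataFrame({
        "node": nodes,
        "degree": [float(deg[n]) for n in nodes],
        "betweenness": [btw[n] for n in nodes],
        "closeness": [clo[n] for n in nodes],
    }).set_index("node")


def composite_hubness(metrics: pd.DataFrame) -> pd.DataFrame:
    """Composite hub scores from the three centralities.

    Each metric is z-scored across nodes (composite_z = mean of the
    three z-scores, so composite_z averages 0 over nodes) and ranked
    descending with average ranks for ties (composite_rank = mean of the
    three ranks). A zero-variance metric contributes z = 0 with a
    warning.
    """
    if len(metrics) < 2:
        raise ValueError("composite hubness needs >= 2 nodes")
    out = metrics.copy()
    zcols, rcols = [], []
    for col in ("degree", "betweenness", "closeness"):
        vals = metrics[col].to_numpy(float)
        sd = vals.std()
        if sd <= 1e-12 * max(1.0, np.abs(vals).max()):
            warnings.warn(f"zero variance in {col}: z contribution set to 0")
            z = np.zeros_like(vals)
        else:
            z = (vals - vals.mean()) / sd
        out[f"z_{col}"] = z
        out[f"rank_{col}"] = stats.rankdata(-vals, method="average")
        zcols.append(f"z_{col}")
        rcols.append(f"rank_{col}")
    out["composite_z"] = out[zcols].mean(axis=1)
    out["composite_rank"] = out[rcols].mean(axis=1)
    return out


def participation_coefficient(net, partition: Partition | dict) -> pd.DataFrame:
    """P_i = 1 - sum_s (k_is / k_i)^2 over modules s; P = 0 for isolated
    nodes. P is 0 for provincial nodes and approaches 1 for connector
    hubs spreading edges evenly over modules."""
    g = _as_graph(net)
    labels = partition.labels if isinstance(partition, Partition) else dict(partition)
    missing = set(g.nodes()) - set(labels)
    if missing:
        raise ValueError(f"partition does not cover nodes: {sorted(missing)}")
    rows = []
    for node in g.nodes():
        k = g.degree(node)
        if k == 0:
            rows.append((node, 0.0))
            continue
        per_module: dict = {}
        for nbr in g.neighbors(node):
            per_module[labels[nbr]] = per_module.get(labels[nbr], 0) + 1
        p = 1.0 - sum((c / k) ** 2 for c in per_module.values())
        rows.append((node, p))
    return pd.DataFrame(rows, columns=["node", "participation"]).set_index("node")


def node_deletion_impact(net) -> pd.DataFrame:
    """Percentage reduction in global efficiency after deleting each node
    (and its edges); efficiency of the reduced graph is defined even if
    the deletion disconnects it (disconnected pairs contribute 0)."""
    g = _as_graph(net)
    if g.number_of_nodes() < 3:
        raise ValueError("node deletion needs >= 3 nodes")
    g0 = global_efficiency(g)
    if g0 == 0:
        raise ValueError("global efficiency is 0: impact undefined")
    rows = []
    for node in list(g.nodes()):
        h = g.copy()
        h.remove_node(node)
        rows.append((node, 100.0 * (g0 - global_efficiency(h)) / g0))
    return pd.DataFrame(rows, columns=["node", "deletion_impact_pct"]).set_index("node")


# ---------------------------------------------------------------------------
# Modularity
# ---------------------------------------------------------------------------

def modularity_q(net, labels: dict, weighted: bool = False) -> float:
    """Newman-Girvan modularity of a partition:
    Q = sum_c [ e_c / m - (d_c / 2m)^2 ] with e_c the (weighted) edge
    mass inside module c and d_c the total (weighted) degree of c."""
    g = _as_graph(net)
    weight = "weight" if weighted else None
    m = g.size(weight=weight)
    if m == 0:
        raise ValueError("modularity undefined on an empty graph")
    deg = dict(g.degree(weight=weight))
    internal: dict = {}
    dc: dict = {}
    for node, d in deg.items():
        c = labels[node]
        dc[c] = dc.get(c, 0.0) + d
    for u, v, w in g.edges(data="weight" if weighted else None, default=1.0):
        if labels[u] == labels[v]:
            internal[labels[u]] = internal.get(labels[u], 0.0) + (w or 1.0)
    q = 0.0
    for c, d in dc.items():
        q += internal.get(c, 0.0) / m - (d / (2.0 * m)) ** 2
    return q


def _canonical_labels(communities, nodes) -> dict:
    labels = {}
    for i, com in enumerate(communities):
        for node in com:
            labels[node] = i
    return {n: labels[n] for n in nodes}


def modularity_louvain(net, n_restarts: int = 10000, seed: int = 0,
                       weighted: bool = False) -> Partition:
    """Best-Q Louvain partition over randomized-order restarts.

    Runs the Louvain algorithm ``n_restarts`` times with independent
    seeded node orders and keeps the partition with the highest
    Newman-Girvan Q (ties broken by first occurrence). Deterministic
    given ``seed``.
    """
    g = _as_graph(net)
    if g.number_of_edges() == 0:
        raise ValueError("Louvain needs at least one edge")
    weight = "weight" if weighted else None
    rng = np.random.default_rng(seed)
    best_q, best_labels = -np.inf, None
    for _ in range(n_restarts):
        comms = nx.community.louvain_communities(
            g, weight=weight, seed=int(rng.integers(2 ** 31 - 1)))
        labels = _canonical_labels(comms, g.nodes())
        q = modularity_q(g, labels, weighted=weighted)
        if q > best_q:
            best_q, best_labels = q, labels
    return Partition(labels=best_labels, q=float(best_q), algorithm="louvain")


def modularity_girvan_newman(net, weighted: bool = False) -> Partition:
    """Girvan-Newman divisive partition: iteratively remove the highest
    edge-betweenness edge and return the dendrogram level with maximal
    Q (the trivial one-module level included)."""
    g = _as_graph(net)
    if g.number_of_edges() == 0:
        raise ValueError("Girvan-Newman needs at least one edge")
    best_labels = _canonical_labels(
        [set(c) for c in nx.connected_components(g)], g.nodes())
    best_q = modularity_q(g, best_labels, weighted=weighted)
    if weighted:
        def most_valuable(graph):
            btw = nx.edge_betweenness_centrality(graph, weight="length")
            return max(btw, key=btw.get)
        _length_attr(g, weighted=True)
        levels = nx.community.girvan_newman(g, most_valuable_edge=most_valuable)
    else:
        levels = nx.community.girvan_newman(g)
    for comms in levels:
        labels = _canonical_labels([set(c) for c in comms], g.nodes())
        q = modularity_q(g, labels, weighted=weighted)
        if q > best_q:
            best_q, best_labels = q, labels
    return Partition(labels=best_labels, q=float(best_q),
                     algorithm="girvan-newman")


# ---------------------------------------------------------------------------
# Null models
# ---------------------------------------------------------------------------

def rewired_null(g: nx.Graph, rng: np.random.Generator,
                 null: str = "degree_preserving") -> nx.Graph:
    """One null draw: degree-preserving (Maslov-Sneppen) double-edge-swap
    rewiring (default) or an Erdos-Renyi graph with matched n and m."""
    if null == "erdos_renyi":
        return nx.gnm_random_graph(g.number_of_nodes(), g.number_of_edges(),
                                   seed=int(rng.integers(2 ** 31 - 1)))
    if null != "degree_preserving":
        raise ValueError("null must be 'degree_preserving' or 'erdos_renyi'")
    h = g.copy()
    m = h.number_of_edges()
    if m < 2:
        return h
    try:
        nx.double_edge_swap(h, nswap=10 * m, max_tries=1000 * m,
                            seed=int(rng.integers(2 ** 31 - 1)))
    except nx.NetworkXError:
        # graphs with no swappable edge pairs (e.g. complete) stay as-is
        pass
    except nx.NetworkXAlgorithmError:
        log.warning("double_edge_swap exhausted max_tries; partial rewiring kept")
    return h


@dataclass
class ModularityNull:
    """Observed Q against a null distribution of Q_rand values."""

    q: float
    q_rand: np.ndarray
    null: str

    @property
    def mean(self) -> float:
        return float(self.q_rand.mean())

    @property
    def sd(self) -> float:
        return float(self.q_rand.std(ddof=1))

    @property
    def zscore(self) -> float:
        if self.sd == 0:
            raise ValueError("null SD is 0: z-score undefined")
        return (self.q - self.mean) / self.sd


def modularity_zscore(net, n_perm: int = 10000, seed: int = 0,
                      null: str = "degree_preserving",
                      n_restarts: int = 10, partition: Partition | None = None
                      ) -> ModularityNull:
    """Standardize modularity against randomly reassigned connections.

    Each of ``n_perm`` null graphs (degree-preserving rewirings by
    default) is re-partitioned with the same Louvain procedure and the
    observed best Q is z-scored against the null Q distribution.
    """
    g = _as_graph(net)
    if g.number_of_edges() < 2:
        raise ValueError("modularity null needs >= 2 edges")
    if n_perm < 2:
        raise ValueError("n_perm must be >= 2 for an SD estimate")
    rng = np.random.default_rng(seed)
    if partition is None:
        partition = modularity_louvain(g, n_restarts=n_restarts,
                                       seed=int(rng.integers(2 ** 31 - 1)))
    q_rand = np.empty(n_perm)
    for i in range(n_perm):
        h = rewired_null(g, rng, null=null)
        if h.number_of_edges() == 0:
            q_rand[i] = 0.0
            continue
        p = modularity_louvain(h, n_restarts=n_restarts,
                               seed=int(rng.integers(2 ** 31 - 1)))
        q_rand[i] = p.q
    return ModularityNull(q=partition.q, q_rand=q_rand, null=null)


# ---------------------------------------------------------------------------
# Small-world index
# ---------------------------------------------------------------------------

@dataclass
class SmallWorldResult:
    c: float
    g: float
    l: float
    c_rand: float
    g_rand: float
    l_rand: float

    @property
    def sigma(self) -> float:
        """(C/C_rand) / (L/L_rand); > 1 signals the small-world regime."""
        return (self.c / self.c_rand) / (self.l / self.l_rand)


def small_world(net, n_rand: int = 10000, seed: int = 0,
                null: str = "degree_preserving",
                allow_disconnected: bool = False) -> SmallWorldResult:
    """Clustering, efficiency and path length against rewiring nulls.

    C, G and L are computed on the network; C_rand, G_rand, L_rand are
    null means over ``n_rand`` degree-preserving rewirings. Null draws
    that disconnect contribute path lengths over connected pairs only.
    """
    g = _as_graph(net)
    if not allow_disconnected and not nx.is_connected(g):
        raise ValueError("small-world analysis requires a connected graph")
    rng = np.random.default_rng(seed)
    c = clustering_coefficient(g)
    eff = global_efficiency(g)
    l = characteristic_path_length(g)
    cr = np.empty(n_rand)
    gr = np.empty(n_rand)
    lr = np.empty(n_rand)
    for i in range(n_rand):
        h = rewired_null(g, rng, null=null)
        cr[i] = clustering_coefficient(h)
        gr[i] = global_efficiency(h)
        lr[i] = characteristic_path_length(h)
    return SmallWorldResult(c=c, g=eff, l=l, c_rand=float(cr.mean()),
                            g_rand=float(gr.mean()), l_rand=float(lr.mean()))


# ---------------------------------------------------------------------------
# Partition similarity (z-rand)
# ---------------------------------------------------------------------------

def _pair_count_stats(sizes: np.ndarray) -> tuple[float, float, float, float]:
    """Falling-factorial tallies of co-clustered ordered tuples."""
    s = sizes.astype(float)
    n2 = (s * (s - 1)).sum()
    n3 = (s * (s - 1) * (s - 2)).sum()
    n4 = (s * (s - 1) * (s - 2) * (s - 3)).sum()
    n22 = ((s * (s - 1)) ** 2).sum()
    return n2, n3, n4, n22


def zrand_similarity(p1, p2, node_order=None) -> float:
    """Standardized pair-counting Rand similarity between two partitions.

    z = (w - E[w]) / SD[w], where w is the number of node pairs
    co-assigned in both partitions and the moments are taken under the
    permutation (hypergeometric) null that relabels one partition's
    nodes uniformly at random while fixing both sets of module sizes.
    """
    l1 = p1.labels if isinstance(p1, Partition) else dict(p1)
    l2 = p2.labels if isinstance(p2, Partition) else dict(p2)
    if set(l1) != set(l2):
        raise ValueError("partitions must cover the same node set")
    nodes = list(l1) if node_order is None else list(node_order)
    a = np.array([l1[n] for n in nodes])
    b = np.array([l2[n] for n in nodes])
    n = len(nodes)
    if n < 4:
        raise ValueError("z-rand needs >= 4 nodes")
    same_a = a[:, None] == a[None, :]
    same_b = b[:, None] == b[None, :]
    triu = np.triu_indices(n, 1)
    w = float((same_a[triu] & same_b[triu]).sum())
    sizes_a = np.unique(a, return_counts=True)[1]
    sizes_b = np.unique(b, return_counts=True)[1]
    m = n * (n - 1) / 2.0
    t1 = (sizes_a * (sizes_a - 1) / 2.0).sum()
    t2 = (sizes_b * (sizes_b - 1) / 2.0).sum()
    n2a, n3a, n4a, n22a = _pair_count_stats(sizes_a)
    n2b, n3b, n4b, n22b = _pair_count_stats(sizes_b)
    e_w = t1 * t2 / m
    # E[w^2]: diagonal + pair-of-pairs sharing one node + disjoint pairs
    share_a = n3a          # ordered (p, q) co-pairs of p1 sharing one node
    share_b = n3b / (n * (n - 1) * (n - 2))
    disj_a = (n4a + n2a ** 2 - n22a) / 4.0
    disj_b = (n4b + n2b ** 2 - n22b) / (n * (n - 1) * (n - 2) * (n - 3))
    e_w2 = t1 * t2 / m + share_a * share_b + disj_a * disj_b
    var_w = e_w2 - e_w ** 2
    if var_w <= 0:
        raise ValueError("degenerate partitions: z-rand variance is 0 "
                         "(e.g. a single-module partition)")
    return (w - e_w) / math.sqrt(var_w)


# ---------------------------------------------------------------------------
# Convenience: the full per-node metric table
# ---------------------------------------------------------------------------

def node_metrics(net, partition: Partition | None = None) -> pd.DataFrame:
    """Centralities + composite hub scores + participation + deletion
    impact in one table (participation requires a partition)."""
    table = composite_hubness(centralities(net))
    table = table.join(node_deletion_impact(net))
    if partition is not None:
        table = table.join(participation_coefficient(net, partition))
    return table
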