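"""Group olfactory network construction.

From cleaned timeseries to a binary group network: pairwise Pearson
correlation with Fisher z transform, per-node global baseline
connectivity, a one-sample t-test of each edge against its baseline,
per-node proportional thresholding (top fraction of each node's
whole-brain connections), seeded admission of candidate regions with at
least one suprathreshold connection to a key olfactory region, and the
cross-modality disconnection control.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from scipy import stats

from .containers import BinaryNetwork, ConnectivityMatrix, RoiTimeseries

log = logging.getLogger(__name__)

#: |r| is capped here before the Fisher transform so z stays finite
R_CAP = 1.0 - 1e-7


def correlation_matrix(ts: RoiTimeseries, level: str = "subject") -> ConnectivityMatrix:
    """Pairwise Pearson correlation over retained scans, Fisher z-transformed.

    Zero-variance ROIs and perfectly correlated pairs are flagged with a
    warning; |r| is capped just below 1 so the transform stays finite.
    """
    x = ts.retained_values()
    if x.shape[0] < 3:
        raise ValueError(f"need >= 3 retained scans, have {x.shape[0]}")
    if x.shape[1] < 2:
        raise ValueError("need >= 2 ROIs")
    sd = x.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = [ts.roi_names[i] for i in dead]
        warnings.warn(f"zero-variance ROI(s) {names}: correlations undefined, "
                      "entries set to 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x, rowvar=False)
    r = np.nan_to_num(r, nan=0.0)
    off = ~np.eye(r.shape[0], dtype=bool)
    if (np.abs(r[off]) >= 1.0).any():
        warnings.warn("perfectly correlated ROI pair: Fisher z capped")
    z = np.arctanh(np.clip(r, -R_CAP, R_CAP))
    np.fill_diagonal(z, 0.0)
    z = (z + z.T) / 2.0
    return ConnectivityMatrix(list(ts.roi_names), z, level=level)


def group_mean_matrix(matrices: list[ConnectivityMatrix]) -> ConnectivityMatrix:
    """Group matrix as the mean of subject Fisher-z matrices."""
    if not matrices:
        raise ValueError("no subject matrices")
    names = matrices[0].node_names
    for m in matrices[1:]:
        if m.node_names != names:
            raise ValueError("subject matrices must share the node set")
    mean = np.mean([m.values for m in matrices], axis=0)
    return ConnectivityMatrix(list(names), mean, level="group")


def global_baseline(whole_brain: ConnectivityMatrix,
                    nodes=None) -> dict[str, float]:
    """Per-node global baseline: mean Fisher z with all other whole-brain
    regions. A pair's baseline is the mean of its two nodes' baselines."""
    n = whole_brain.n_nodes
    if n < 2:
        raise ValueError("whole-brain matrix needs >= 2 nodes")
    sums = whole_brain.values.sum(axis=1)  # diagonal is 0
    per_node = sums / (n - 1)
    nodes = whole_brain.node_names if nodes is None else nodes
    idx = whole_brain.index_of(nodes)
    return {name: float(per_node[i]) for name, i in zip(nodes, idx)}


def pair_baseline(baselines: dict[str, float], a: str, b: str) -> float:
    return 0.5 * (baselines[a] + baselines[b])


def edge_ttest(subject_matrices: list[ConnectivityMatrix],
               subject_baselines: list[dict[str, float]],
               nodes=None) -> tuple[np.ndarray, np.ndarray]:
    """One-sample t-test across subjects of (pair z - pair baseline).

    Returns symmetric matrices of t statistics and one-tailed p-values
    for exceedance over baseline, over ``nodes`` (default: all nodes of
    the subject matrices). Zero-variance pairs with a positive mean are
    capped at t = +inf, p = 0 (and the reverse at p = 1).
    """
    if len(subject_matrices) < 2:
        raise ValueError("t-test needs >= 2 subjects")
    if len(subject_baselines) != len(subject_matrices):
        raise ValueError("one baseline dict per subject required")
    nodes = subject_matrices[0].node_names if nodes is None else list(nodes)
    k = len(nodes)
    diffs = np.empty((len(subject_matrices), k, k))
    for s, (mat, base) in enumerate(zip(subject_matrices, subject_baselines)):
        idx = mat.index_of(nodes)
        sub = mat.values[np.ix_(idx, idx)]
        b = np.array([base[n] for n in nodes])
        diffs[s] = sub - 0.5 * (b[:, None] + b[None, :])
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean / (sd / np.sqrt(diffs.shape[0]))
    t[np.isnan(t)] = 0.0  # mean 0, sd 0: no evidence either way
    p = stats.t.sf(t, df=diffs.shape[0] - 1)
    p[np.isposinf(t)] = 0.0
    p[np.isneginf(t)] = 1.0
    np.fill_diagonal(t, 0.0)
    np.fill_diagonal(p, 0.5)
    return t, p


def per_node_retention(n_context: int, density: float) -> int:
    """Edges retained per node: k = floor(density * (n_context - 1))."""
    k = int(np.floor(density * (n_context - 1)))
    if k < 1:
        raise ValueError(f"density {density} retains no edges for "
                         f"{n_context} nodes")
    return k


def threshold_proportional(matrix: ConnectivityMatrix, density: float,
                           rule: str = "union") -> BinaryNetwork:
    """Per-node proportional thresholding of a connectivity matrix.

    For each node the k = floor(density * (N - 1)) strongest connections
    are marked; an edge is suprathreshold iff it is marked from at least
    one endpoint (``rule='union'``) or from both (``rule='and'``). Rank
    ties are broken by lexicographic node-name order for determinism.
    """
    if not 0 < density < 1:
        raise ValueError("density must lie in (0, 1)")
    if rule not in ("union", "and"):
        raise ValueError("rule must be 'union' or 'and'")
    n = matrix.n_nodes
    k = per_node_retention(n, density)
    # lexicographic tiebreak: stable sort on names first, then on -z
    name_order = np.argsort(np.array(matrix.node_names))
    marked = np.zeros((n, n), dtype=bool)
    vals = matrix.values.copy()
    np.fill_diagonal(vals, -np.inf)
    for i in range(n):
        row = vals[i, name_order]
        top = name_order[np.argsort(-row, kind="stable")[:k]]
        marked[i, top] = True
    adj = (marked | marked.T) if rule == "union" else (marked & marked.T)
    return BinaryNetwork(list(matrix.node_names), adj.astype(np.int8))


def build_seeded_network(adjacency: BinaryNetwork, key_nodes,
                         candidate_nodes) -> BinaryNetwork:
    """Admit candidates with >= 1 suprathreshold connection to a key node.

    The network is the induced subgraph over all key nodes (always
    retained) plus the admitted candidates; node roles annotate keys,
    admitted secondaries, and rejected candidates.
    """
    key_nodes = list(key_nodes)
    candidate_nodes = list(candidate_nodes)
    if not key_nodes:
        raise ValueError("empty key node set")
    overlap = set(key_nodes) & set(candidate_nodes)
    if overlap:
        raise ValueError(f"candidates must be disjoint from keys: {sorted(overlap)}")
    lookup = {n: i for i, n in enumerate(adjacency.node_names)}
    missing = [n for n in key_nodes + candidate_nodes if n not in lookup]
    if missing:
        raise KeyError(f"nodes absent from adjacency: {missing}")
    key_idx = np.array([lookup[n] for n in key_nodes])
    admitted = [c for c in candidate_nodes
                if adjacency.adjacency[lookup[c], key_idx].any()]
    members = key_nodes + admitted
    net = adjacency.subnetwork(members)
    net.roles = {**{n: "key" for n in key_nodes},
                 **{n: "secondary" for n in admitted},
                 **{n: "rejected" for n in candidate_nodes if n not in admitted}}
    # rejected nodes are annotated but not part of the network node set
    net.roles = {n: r for n, r in net.roles.items() if n in members}
    rejected = [c for c in candidate_nodes if c not in admitted]
    log.info("seeded admission: %d keys, %d/%d candidates admitted, %d rejected",
             len(key_nodes), len(admitted), len(candidate_nodes), len(rejected))
    net.rejected_nodes = rejected  # type: ignore[attr-defined]
    return net


def cross_modality_control(matrix: ConnectivityMatrix, set_a, set_b,
                           densities=(0.05, 0.10, 0.15),
                           rule: str = "union") -> dict[float, int]:
    """Count suprathreshold edges crossing two disjoint node sets at each
    density (thresholds are taken in the full context of ``matrix``)."""
    set_a, set_b = list(set_a), list(set_b)
    if set(set_a) & set(set_b):
        raise ValueError("node sets must be disjoint")
    counts = {}
    for d in densities:
        net = threshold_proportional(matrix, d, rule=rule)
        ia = net.subnetwork(set_a + set_b)  # induced, ordered a then b
        block = ia.adjacency[:len(set_a), len(set_a):]
        counts[float(d)] = int(block.sum())
    return counts


def network_density(net: BinaryNetwork) -> float:
    """Density as a percentage: 100 * E / (n(n-1)/2)."""
    n = net.n_nodes
    if n < 2:
        raise ValueError("density needs >= 2 nodes")
    return 100.0 * net.n_edges / (n * (n - 1) / 2)
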