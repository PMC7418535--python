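"""Validation study: weighted subject networks, d', and permutation
Spearman linkage.

Subject-level correlation matrices are masked by the group binary
template (|r| weights), weighted small-world metrics are extracted, 2AFC
odor discrimination performance is summarized as d' = Z(hit) - Z(false
alarm) over the extreme mixtures, and associations are tested with
Spearman correlations against permutation nulls (n = 10,000, one-tailed
at the 95th percentile by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import BinaryNetwork, ConnectivityMatrix
from .graphmetrics import (clustering_coefficient, global_efficiency,
                           modularity_louvain, zrand_similarity)

EXTREME_A = "80/20"  # dominantly odor A
EXTREME_B = "20/80"  # dominantly odor B


def mask_subject_network(subject: ConnectivityMatrix,
                         template: BinaryNetwork):
    """Sparse weighted network: |subject r| where the template has an
    edge, 0 elsewhere. Returns a networkx graph over the template nodes
    with ``weight`` attributes."""
    import networkx as nx

    idx = subject.index_of(template.node_names)
    r = np.tanh(subject.values[np.ix_(idx, idx)])
    w = np.abs(r) * template.adjacency
    g = nx.Graph()
    g.add_nodes_from(template.node_names)
    ii, jj = np.nonzero(np.triu(template.adjacency, 1))
    for i, j in zip(ii, jj):
        g.add_edge(template.node_names[i], template.node_names[j],
                   weight=float(w[i, j]))
    return g


def weighted_small_world_metrics(w) -> tuple[float, float]:
    """(G_w, C_w): weighted global efficiency and clustering of a masked
    subject network."""
    if w.number_of_nodes() < 3:
        raise ValueError("need >= 3 nodes")
    if all(d.get("weight", 0) == 0 for _, _, d in w.edges(data=True)):
        raise ValueError("all-zero network: weighted metrics undefined")
    return global_efficiency(w, weighted=True), clustering_coefficient(w, weighted=True)


@dataclass
class BehaviorSummary:
    """Signal-detection summary of the extreme-mixture 2AFC trials."""

    hit_rate: float
    fa_rate: float
    dprime: float
    n_hit: int
    n_fa: int
    n_trials_a: int
    n_trials_b: int


def dprime(trials: pd.DataFrame, loglinear: bool = True) -> BehaviorSummary:
    """d' = Z(hit) - Z(false alarm) from the extreme mixtures only.

    A hit is an "A" response on dominantly-A (80/20) trials; a false
    alarm is an "A" response on dominantly-B (20/80) trials. Middle
    mixtures are recorded but excluded. Rates are log-linear corrected
    (0.5 added to each count, 1 to each denominator) so 0/1 rates stay
    finite.
    """
    a_trials = trials[trials["mixture"] == EXTREME_A]
    b_trials = trials[trials["mixture"] == EXTREME_B]
    if len(a_trials) == 0 or len(b_trials) == 0:
        raise ValueError("both extreme mixtures (80/20 and 20/80) required")
    n_hit = int((a_trials["response"] == "A").sum())
    n_fa = int((b_trials["response"] == "A").sum())
    na, nb = len(a_trials), len(b_trials)
    if loglinear:
        hit = (n_hit + 0.5) / (na + 1)
        fa = (n_fa + 0.5) / (nb + 1)
    else:
        hit, fa = n_hit / na, n_fa / nb
        if hit in (0.0, 1.0) or fa in (0.0, 1.0):
            raise ValueError("0/1 rate without correction: d' infinite")
    d = float(stats.norm.ppf(hit) - stats.norm.ppf(fa))
    return BehaviorSummary(hit_rate=hit, fa_rate=fa, dprime=d, n_hit=n_hit,
                           n_fa=n_fa, n_trials_a=na, n_trials_b=nb)


@dataclass
class CorrelationTestResult:
    rho: float
    p: float
    n_perm: int
    seed: int
    tail: str = "greater"


def spearman_perm(x, y, n_perm: int = 10000, seed: int = 0,
                  tail: str = "greater") -> CorrelationTestResult:
    """Spearman rank correlation with a permutation null.

    The observed rho is compared with rho under ``n_perm`` random
    permutations of ``y``; significance at p < 0.05 corresponds to the
    95th percentile of the null for the default one-tailed test
    (``tail='two-sided'`` compares |rho|). The returned p uses the
    add-one permutation convention, so p is in (0, 1].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError("need >= 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: rank correlation undefined")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx_c = (rx - rx.mean()) / (rx.std() * np.sqrt(x.size))
    ry_c = (ry - ry.mean()) / (ry.std() * np.sqrt(x.size))
    rho = float(np.dot(rx_c, ry_c))  # Pearson correlation of midranks
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(ry_c, (n_perm, 1)), axis=1)
    null = perms @ rx_c
    if tail == "greater":
        exceed = int((null >= rho).sum())
    elif tail == "two-sided":
        exceed = int((np.abs(null) >= abs(rho)).sum())
    else:
        raise ValueError("tail must be 'greater' or 'two-sided'")
    p = (exceed + 1) / (n_perm + 1)
    return CorrelationTestResult(rho=rho, p=float(p), n_perm=n_perm,
                                 seed=seed, tail=tail)


def _edge_vector(mat: ConnectivityMatrix, node_names, edge_mask: np.ndarray) -> np.ndarray:
    idx = mat.index_of(node_names)
    sub = mat.values[np.ix_(idx, idx)]
    return sub[edge_mask]


def matrix_concordance(a: ConnectivityMatrix, b: ConnectivityMatrix,
                       edge_set: BinaryNetwork | None = None,
                       n_perm: int = 10000, seed: int = 0,
                       method: str = "spearman"):
    """Concordance of two connectivity matrices over designated entries.

    By default the unique off-diagonal entries of the ``edge_set``
    template are compared (all unique off-diagonal pairs if no template
    is given), with Spearman rho permutation-tested; ``method='pearson'``
    returns the plain Pearson R instead (no permutation test).
    """
    if edge_set is not None:
        names = edge_set.node_names
        mask = np.triu(edge_set.adjacency, 1) > 0
        if not mask.any():
            raise ValueError("edge set is empty")
    else:
        names = a.node_names
        mask = np.triu(np.ones((len(names), len(names)), dtype=bool), 1)
    va = _edge_vector(a, names, mask)
    vb = _edge_vector(b, names, mask)
    if method == "pearson":
        return float(np.corrcoef(va, vb)[0, 1])
    if method != "spearman":
        raise ValueError("method must be 'spearman' or 'pearson'")
    return spearman_perm(va, vb, n_perm=n_perm, seed=seed)


@dataclass
class CohortConsistency:
    """Subject-level modular consistency against the group partition."""

    subject_partitions: list
    zrand_to_group: np.ndarray
    zrand_pairwise: np.ndarray
    null_zrand: np.ndarray
    module_counts: np.ndarray

    @property
    def mean_zrand_to_group(self) -> float:
        return float(self.zrand_to_group.mean())

    @property
    def mean_zrand_pairwise(self) -> float:
        return float(self.zrand_pairwise.mean()) if self.zrand_pairwise.size else float("nan")

    def test_vs_null(self):
        """Two-sample t-test of observed z-rand values against the
        permuted-label null."""
        return stats.ttest_ind(self.zrand_to_group, self.null_zrand,
                               equal_var=False)


def cohort_modularity_consistency(subject_networks, group_partition,
                                  seed: int = 0, n_restarts: int = 20,
                                  n_null_per_subject: int = 10) -> CohortConsistency:
    """Louvain on each subject's weighted network, z-rand against the
    group partition and pairwise across subjects, with a permuted-label
    null (subject partitions with node assignments shuffled)."""
    subject_networks = list(subject_networks)
    if len(subject_networks) < 2:
        raise ValueError("need >= 2 subjects")
    rng = np.random.default_rng(seed)
    partitions = []
    for g in subject_networks:
        p = modularity_louvain(g, n_restarts=n_restarts,
                               seed=int(rng.integers(2 ** 31 - 1)),
                               weighted=True)
        if p.n_modules == 1:
            warnings.warn("degenerate single-module subject partition")
        partitions.append(p)
    nodes = list(group_partition.labels)
    zg, null = [], []
    counts = []
    for p in partitions:
        counts.append(p.n_modules)
        try:
            zg.append(zrand_similarity(p, group_partition))
        except ValueError:
            zg.append(0.0)
        for _ in range(n_null_per_subject):
            perm = rng.permutation(nodes)
            shuffled = {m: p.labels[n] for m, n in zip(nodes, perm)}
            try:
                null.append(zrand_similarity(shuffled, group_partition.labels))
            except ValueError:
                null.append(0.0)
    pairwise = []
    for i in range(len(partitions)):
        for j in range(i + 1, len(partitions)):
            try:
                pairwise.append(zrand_similarity(partitions[i], partitions[j]))
            except ValueError:
                pairwise.append(0.0)
    return CohortConsistency(subject_partitions=partitions,
                             zrand_to_group=np.array(zg),
                             zrand_pairwise=np.array(pairwise),
                             null_zrand=np.array(null),
                             module_counts=np.array(counts))
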