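"""Shared fixtures.

The expensive session fixture runs the planted-structure recovery
pipeline (whole-brain synthetic context at study scale: 28 study ROIs
among 627 regions, 4 runs x 1200 scans) over 20 seeds once; the
planted-recovery, hub-recovery and density-sweep tests all consume it.
"""

import networkx as nx
import numpy as np
import pytest

from olfnet import graphmetrics as gm
from olfnet import netbuild as nb
from olfnet import preprocess as pp
from olfnet import simulate as sim

N_PLANTED_SEEDS = 20


@pytest.fixture(scope="session")
def planted_runs():
    """Full pipeline (simulate -> clean -> correlate -> threshold ->
    admit -> partition -> modularity null) for 20 independent seeds at
    the study's planted conditions (intra 0.5, inter 0.1, 28 study ROIs,
    4 x 1200 scans)."""
    candidates = [n for n in sim.study_roi_names() if n not in sim.KEY_NODES]
    runs = []
    for seed in range(N_PLANTED_SEEDS):
        spec = sim.default_study_spec(seed=1000 + seed)
        ts = sim.generate_modular_timeseries(spec)
        rng = np.random.default_rng(2000 + seed)
        motion = np.vstack([
            sim.inject_motion(spec.scans_per_run,
                              rng.choice(spec.scans_per_run, 12, replace=False),
                              1.0, seed=int(rng.integers(2 ** 31 - 1)))
            for _ in range(spec.n_runs)])
        clean = pp.clean_timeseries(ts, motion)
        whole = nb.correlation_matrix(clean, level="group")
        adjacency = nb.threshold_proportional(whole, 0.05)
        net = nb.build_seeded_network(adjacency, sim.KEY_NODES, candidates)
        partition = gm.modularity_louvain(net, n_restarts=50, seed=seed)
        null = gm.modularity_zscore(net, n_perm=100, seed=seed,
                                    n_restarts=3, partition=partition)
        runs.append({
            "seed": seed,
            "whole": whole,
            "network": net,
            "partition": partition,
            "zscore": null.zscore,
            "admitted": sorted(n for n, r in net.roles.items()
                               if r == "secondary"),
        })
    return runs


@pytest.fixture(scope="session")
def planted_template(planted_runs):
    """A group network from the first planted run, used as the cohort
    template."""
    return planted_runs[0]["network"]


@pytest.fixture
def karate():
    g = nx.karate_club_graph()
    return nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes()})


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
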