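"""Configured, logged, reproducible end-to-end pipeline.

``run_pipeline`` executes simulate -> preprocess -> netbuild -> graph ->
behavior per the stage toggles, logs every threshold actually applied,
writes all artifacts plus a manifest with per-stage wall-clock times and
output checksums, and a resolved copy of the configuration. Every random
draw in any stage flows from the single top-level seed via named
substreams.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as bhv
from . import graphmetrics as gm
from . import netbuild as nb
from . import preprocess as pp
from . import simulate as sim
from .config import PipelineConfig
from .containers import BinaryNetwork, ConnectivityMatrix, Partition

log = logging.getLogger(__name__)


def stage_seed(root_seed: int, stage: str) -> int:
    """Named substream seed derived from the top-level seed (< 2**31)."""
    ss = np.random.SeedSequence([int(root_seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2 ** 31 - 1))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    seed: int
    stages: list = field(default_factory=list)
    outputs: dict = field(default_factory=dict)
    wall_clock_s: dict = field(default_factory=dict)

    def record(self, stage: str, t0: float, outdir: Path, files: list) -> None:
        self.stages.append(stage)
        self.wall_clock_s[stage] = round(time.perf_counter() - t0, 3)
        for f in files:
            self.outputs[str(f.relative_to(outdir))] = _sha256(f)

    def to_json(self, path: Path) -> None:
        import olfnet

        payload = {"seed": self.seed, "version": olfnet.__version__,
                   "stages": self.stages, "wall_clock_s": self.wall_clock_s,
                   "outputs": self.outputs}
        path.write_text(json.dumps(payload, indent=2))


@dataclass
class PipelineResult:
    """In-memory results of a pipeline run (also written to disk)."""

    manifest: RunManifest
    timeseries: object = None
    clean: object = None
    whole_brain: ConnectivityMatrix | None = None
    network: BinaryNetwork | None = None
    partition: Partition | None = None
    modularity_null: object = None
    small_world: object = None
    node_metrics: pd.DataFrame | None = None
    cross_modality: dict | None = None
    behavior_table: pd.DataFrame | None = None
    behavior_tests: dict | None = None


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> PipelineResult:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "resolved_config.yaml")
    manifest = RunManifest(seed=config.seed)
    result = PipelineResult(manifest=manifest)
    cfg = config

    ts = motion = None
    if cfg.stages.simulate:
        t0 = time.perf_counter()
        ts, motion = _stage_simulate(cfg)
        files = []
        if cfg.write_timeseries:
            ts.to_tsv(outdir / "timeseries.tsv")
            pd.DataFrame(motion).to_csv(outdir / "motion.tsv", sep="\t",
                                        index=False, header=False)
            files = [outdir / "timeseries.tsv", outdir / "motion.tsv"]
        manifest.record("simulate", t0, outdir, files)
        result.timeseries = ts

    clean = ts
    if cfg.stages.preprocess:
        if ts is None:
            raise RuntimeError("preprocess stage needs simulate stage output")
        t0 = time.perf_counter()
        log.info("preprocess thresholds: FD %.2f mm, bandpass %.3f-%.3f Hz",
                 cfg.preprocess.fd_threshold_mm, cfg.preprocess.bandpass_low_hz,
                 cfg.preprocess.bandpass_high_hz)
        clean = pp.clean_timeseries(
            ts, motion,
            fd_threshold=cfg.preprocess.fd_threshold_mm,
            low=cfg.preprocess.bandpass_low_hz,
            high=cfg.preprocess.bandpass_high_hz,
            order=cfg.preprocess.filter_order,
            bandpass_before_regression=cfg.preprocess.bandpass_before_regression)
        manifest.record("preprocess", t0, outdir, [])
        result.clean = clean

    if cfg.stages.netbuild:
        if clean is None:
            raise RuntimeError("netbuild stage needs timeseries input")
        t0 = time.perf_counter()
        whole = nb.correlation_matrix(clean, level="group")
        log.info("netbuild: density %.3f (%s rule) over %d-node context",
                 cfg.netbuild.density, cfg.netbuild.threshold_rule, whole.n_nodes)
        adjacency = nb.threshold_proportional(whole, cfg.netbuild.density,
                                              rule=cfg.netbuild.threshold_rule)
        candidates = [n for n in sim.study_roi_names() if n not in sim.KEY_NODES]
        network = nb.build_seeded_network(adjacency, sim.KEY_NODES, candidates)
        network.to_json(outdir / "network.json")
        roi_matrix = whole.submatrix(sim.study_roi_names())
        roi_matrix.to_csv(outdir / "roi_matrix.csv")
        control_set = [n for n in sim.STUDY_MODULES["visual"]
                       if n not in network.node_names]
        cross = nb.cross_modality_control(
            whole, list(network.node_names), control_set,
            densities=cfg.netbuild.control_densities,
            rule=cfg.netbuild.threshold_rule)
        (outdir / "cross_modality.json").write_text(json.dumps(
            {str(k): v for k, v in cross.items()}, indent=2))
        manifest.record("netbuild", t0, outdir,
                        [outdir / "network.json", outdir / "roi_matrix.csv",
                         outdir / "cross_modality.json"])
        result.whole_brain = whole
        result.network = network
        result.cross_modality = cross

    if cfg.stages.graph:
        if result.network is None:
            raise RuntimeError("graph stage needs the built network")
        t0 = time.perf_counter()
        g = cfg.graph
        partition = gm.modularity_louvain(result.network,
                                          n_restarts=g.n_restarts,
                                          seed=stage_seed(cfg.seed, "louvain"))
        null = gm.modularity_zscore(result.network, n_perm=g.n_perm,
                                    seed=stage_seed(cfg.seed, "modularity-null"),
                                    null=g.null_model, partition=partition)
        partition.zscore = null.zscore
        log.info("modularity: Q=%.3f (cutoff %.2f), Z=%.2f (cutoff %.1f), "
                 "%d modules", partition.q, g.q_cutoff, null.zscore,
                 g.z_cutoff, partition.n_modules)
        sw = gm.small_world(result.network, n_rand=g.n_rand,
                            seed=stage_seed(cfg.seed, "small-world"),
                            null=g.null_model, allow_disconnected=True)
        metrics = gm.node_metrics(result.network, partition)
        partition.to_json(outdir / "partition.json")
        metrics.to_csv(outdir / "node_metrics.csv")
        pd.DataFrame({"q_rand": null.q_rand}).to_csv(
            outdir / "modularity_null.csv", index=False)
        (outdir / "small_world.json").write_text(json.dumps({
            "C": sw.c, "G": sw.g, "L": sw.l, "C_rand": sw.c_rand,
            "G_rand": sw.g_rand, "L_rand": sw.l_rand, "sigma": sw.sigma},
            indent=2))
        manifest.record("graph", t0, outdir,
                        [outdir / "partition.json", outdir / "node_metrics.csv",
                         outdir / "modularity_null.csv", outdir / "small_world.json"])
        result.partition = partition
        result.modularity_null = null
        result.small_world = sw
        result.node_metrics = metrics

    if cfg.stages.behavior:
        if result.network is None or result.partition is None:
            raise RuntimeError("behavior stage needs the network and partition")
        t0 = time.perf_counter()
        b = cfg.behavior
        # the synthetic validation cohort measures the same underlying
        # connectivity: subject matrices scatter around the group |r|
        roi_net_z = result.whole_brain.submatrix(result.network.node_names)
        group_weights = np.abs(np.tanh(roi_net_z.values)) * result.network.adjacency
        cohort = sim.generate_cohort(
            b.n_subjects, result.network, b.coupling_rho,
            seed=stage_seed(cfg.seed, "cohort"),
            template_weights=group_weights,
            trials_per_mixture=b.trials_per_mixture)
        rows = []
        masked = []
        for i, subj in enumerate(cohort.subjects):
            w = bhv.mask_subject_network(subj.matrix, result.network)
            masked.append(w)
            gw, cw = bhv.weighted_small_world_metrics(w)
            summary = bhv.dprime(subj.trials)
            rows.append((i, gw, cw, summary.dprime, subj.true_dprime))
        table = pd.DataFrame(rows, columns=["subject", "G_w", "C_w",
                                            "dprime", "true_dprime"])
        tests = {}
        test_c = bhv.spearman_perm(table["C_w"], table["dprime"],
                                   n_perm=b.n_perm,
                                   seed=stage_seed(cfg.seed, "spearman-cw"))
        test_g = bhv.spearman_perm(table["G_w"], table["dprime"],
                                   n_perm=b.n_perm,
                                   seed=stage_seed(cfg.seed, "spearman-gw"))
        tests["clustering_vs_dprime"] = {"rho": test_c.rho, "p": test_c.p}
        tests["efficiency_vs_dprime"] = {"rho": test_g.rho, "p": test_g.p}
        group_b = nb.group_mean_matrix([s.matrix for s in cohort.subjects])
        roi_net_matrix = result.whole_brain.submatrix(result.network.node_names)
        conc = bhv.matrix_concordance(roi_net_matrix, group_b,
                                      edge_set=result.network,
                                      n_perm=b.n_perm,
                                      seed=stage_seed(cfg.seed, "concordance"))
        tests["group_concordance"] = {"rho": conc.rho, "p": conc.p}
        consistency = bhv.cohort_modularity_consistency(
            masked, result.partition,
            seed=stage_seed(cfg.seed, "cohort-modularity"))
        tests["mean_zrand_to_group"] = consistency.mean_zrand_to_group
        tests["mean_zrand_pairwise"] = consistency.mean_zrand_pairwise
        tests["modal_subject_module_count"] = int(
            pd.Series(consistency.module_counts).mode().iloc[0])
        table.to_csv(outdir / "behavior_metrics.csv", index=False)
        (outdir / "behavior_tests.json").write_text(json.dumps(tests, indent=2))
        manifest.record("behavior", t0, outdir,
                        [outdir / "behavior_metrics.csv",
                         outdir / "behavior_tests.json"])
        result.behavior_table = table
        result.behavior_tests = tests

    manifest.to_json(outdir / "manifest.json")
    return result


def _stage_simulate(cfg: PipelineConfig):
    s = cfg.simulate
    spec = sim.default_study_spec(
        seed=stage_seed(cfg.seed, "timeseries"),
        n_background=s.n_background, intra=s.intra_corr, inter=s.inter_corr,
        n_runs=s.n_runs, scans_per_run=s.scans_per_run,
        repetition_time=s.repetition_time, ar_coeff=s.ar_coeff)
    ts = sim.generate_modular_timeseries(spec)
    rng = np.random.default_rng(stage_seed(cfg.seed, "motion"))
    chunks = []
    for i, (run, idx) in enumerate(ts.iter_runs()):
        n = idx.size
        n_spikes = int(round(s.spike_fraction * n))
        spikes = rng.choice(n, size=n_spikes, replace=False) if n_spikes else []
        chunks.append(sim.inject_motion(n, spikes, s.spike_size_mm,
                                        seed=int(rng.integers(2 ** 31 - 1))))
    return ts, np.vstack(chunks)


# ---------------------------------------------------------------------------
# Density sweep
# ---------------------------------------------------------------------------

@dataclass
class DensitySweepResult:
    densities: list
    networks: dict
    partitions: dict
    assignments: pd.DataFrame      # node x density module table (NaN = out)
    zrand_to_reference: dict
    reference_density: float

    @property
    def module_counts(self) -> dict:
        return {d: p.n_modules for d, p in self.partitions.items()}


def density_sweep(whole_brain: ConnectivityMatrix, key_nodes, candidate_nodes,
                  grid, seed: int = 0, reference_density: float = 0.05,
                  n_restarts: int = 100, rule: str = "union") -> DensitySweepResult:
    """Rebuild the seeded network and its Louvain partition at each
    density in ``grid`` and compare every partition with the
    reference-density partition by z-rand over the shared node set.

    Nodes absent from a density's network ("no longer connected") appear
    as NaN in the assignment table.
    """
    grid = [float(d) for d in grid]
    if any(not 0 < d < 1 for d in grid):
        raise ValueError("grid densities must lie in (0, 1)")
    if reference_density not in grid:
        grid = sorted(grid + [reference_density])
    rng = np.random.default_rng(seed)
    networks, partitions = {}, {}
    for d in grid:
        adjacency = nb.threshold_proportional(whole_brain, d, rule=rule)
        net = nb.build_seeded_network(adjacency, key_nodes, candidate_nodes)
        networks[d] = net
        partitions[d] = gm.modularity_louvain(
            net, n_restarts=n_restarts, seed=int(rng.integers(2 ** 31 - 1)))
    all_nodes = list(key_nodes) + list(candidate_nodes)
    table = pd.DataFrame(index=all_nodes,
                         columns=[f"{d:g}" for d in grid], dtype=float)
    for d in grid:
        for node, label in partitions[d].labels.items():
            table.loc[node, f"{d:g}"] = label
    ref = partitions[reference_density]
    zrand = {}
    for d in grid:
        if d == reference_density:
            continue
        shared = [n for n in partitions[d].labels if n in ref.labels]
        if len(shared) < 4:
            zrand[d] = float("nan")
            continue
        p1 = {n: partitions[d].labels[n] for n in shared}
        p2 = {n: ref.labels[n] for n in shared}
        try:
            zrand[d] = gm.zrand_similarity(p1, p2)
        except ValueError:
            zrand[d] = float("nan")
    return DensitySweepResult(densities=grid, networks=networks,
                              partitions=partitions, assignments=table,
                              zrand_to_reference=zrand,
                              reference_density=reference_density)
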