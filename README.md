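# olfnet

Resting-state functional connectome analysis of the human olfactory
network: a tested, reusable implementation of the full analysis chain
from ROI-averaged BOLD timeseries to a characterized olfactory network
and its link to odor discrimination behavior.

## The problem

The human olfactory system is distributed over many small cortical and
subcortical structures (piriform cortex, olfactory tubercle, entorhinal
cortex, amygdala, orbitofrontal and insular parcels, ...) that standard
whole-brain resting-state analyses resolve poorly. A seeded network
approach fixes this: starting from the primary olfactory regions that
receive direct bulbar input, candidate regions are admitted into the
network if their spontaneous BOLD fluctuations couple strongly enough
with a seed, and the resulting group network is characterized with
graph theory — community structure, small-world organization, hubs,
and resilience — and finally linked to perceptual performance.

`olfnet` implements that chain for anyone working with ROI timeseries
(rows = scans, columns = named ROIs), and ships a synthetic-data module
that emulates the statistical structure of such a study (planted
modular covariance inside a whole-brain background, motion spikes, a
signal-detection observer), so every stage is exercisable end-to-end
with no data download and with known ground truth.

## The model

**Cleaning.** Per run, each ROI series is mean-centered and whitened,
bandpass filtered (zero-phase Butterworth, 0.01–0.08 Hz), residualized
on 24 motion regressors (6 rigid-body parameters, their one-scan lags,
and the squares of those 12), and scrubbed: scans with framewise
displacement

&nbsp;&nbsp;&nbsp;&nbsp;FDᵢ = |Δd_ix| + |Δd_iy| + |Δd_iz| + |Δαᵢ| + |Δβᵢ| + |Δγᵢ| > 0.5 mm

are dropped (rotations in mm-equivalents, 50-mm-sphere convention).

**Network construction.** Pairwise Pearson correlations over retained
scans are Fisher-transformed, z = atanh(r). Each edge is tested against
its *global baseline* (mean z of its two endpoints with all other
whole-brain regions), and each node's top 5% of whole-brain connections
is marked; an ROI-pair edge is suprathreshold if either endpoint marks
it. Candidate regions with at least one suprathreshold connection to a
key olfactory seed are admitted; the group network is the induced
subgraph. A cross-modality control counts suprathreshold edges to
visual cortex at densities 5/10/15%.

**Graph characterization.** Louvain and Girvan–Newman modularity Q
(cutoff 0.3) with a permutation z-score against degree-preserving
(Maslov–Sneppen) rewiring nulls (Z > 3 ⇒ subnetworks); clustering C,
global efficiency G, characteristic path length L, and the small-world
index σ = (C/C_rand)/(L/L_rand); degree, betweenness, and closeness
centralities aggregated into composite hub z-scores and ranks;
participation coefficient P_i = 1 − Σ_s (k_is/k_i)²; and node-deletion
impact on G. Partitions are compared with the standardized
pair-counting Rand similarity (z-rand) under the exact permutation
null.

**Behavioral linkage.** Subject matrices are masked by the group binary
template (|r| weights), weighted C and G extracted, 2AFC odor
discrimination summarized as d′ = Φ⁻¹(hit) − Φ⁻¹(false alarm) over the
extreme mixtures (log-linear corrected), and associations tested with
Spearman ρ against 10,000-permutation nulls.

## Worked example

```bash
olfnet run-all --seed 7 --out demo/
```

runs the whole chain on synthetic study-scale data (627 regions, of
which 28 are study ROIs; 4 runs × 1200 scans; planted three-module
olfactory structure with two bridging hubs) and prints

```
network: 21 nodes, 88 edges (41.9% density)
modularity: Q=0.372 Z=17.51 modules=3
```

i.e. the seeded admission accepted the 15 planted secondary regions
(plus the 6 seeds) and rejected the 7 decorrelated visual-control
parcels; the network splits into 3 modules far beyond the rewiring
null. `demo/` then contains, among others:

* `network.json` — nodes, edges, and key/secondary role annotations;
* `partition.json` — module labels, Q = 0.372, Z = 17.5;
* `small_world.json` — C = 0.891 vs C_rand = 0.537, G = 0.710 vs
  G_rand = 0.709, σ = 1.66: markedly higher clustering than
  degree-matched random graphs at essentially random-graph efficiency,
  the small-world signature;
* `node_metrics.csv` — the two planted hubs (AMY, INSa) take composite
  ranks 1–2, participation ≈ 0.65 (connector hubs), and the two
  largest deletion impacts (7.2% and 5.2% efficiency loss; every other
  node < 1%);
* `cross_modality.json` — 0 suprathreshold edges to visual cortex at
  the 5% density;
* `behavior_tests.json` — subject-level modularity consistency
  (modal module count 3, mean z-rand to the group partition 9.9) and
  the Spearman linkage of weighted clustering/efficiency with d′.

The default configuration uses the full 10,000 restarts/permutations
and takes ~10 minutes; pass `--config` with smaller
`graph.n_restarts`/`n_perm`/`n_rand` for a fast pass (see
`olfnet.config.PipelineConfig` for every threshold and its default).
`olfnet sweep` repeats network construction over the 4–10% density
grid and emits the node × density module-assignment table.

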