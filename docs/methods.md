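# Methods

This note records the models, conventions, parameter choices and known
limitations behind `olfnet`, in the order the pipeline runs.

## Synthetic data: what is emulated, and what is not

The generator (`olfnet.simulate`) produces every input the real study
obtained from scanners and button boxes, with controllable ground
truth.

**Node signals.** ROI timeseries are zero-mean, unit-variance Gaussian
draws from a planted correlation matrix, temporally white by default.
An optional AR(1) recursion (`ar_coeff`, default 0) adds temporal
smoothness with the same coefficient for every node, which leaves the
cross-node correlation matrix untouched; it exists so the bandpass
stage has band-limited content to attenuate when that matters. The
implied correlation matrix is Cholesky-checked at generation; an
invalid specification is rejected with the offending parameters named,
never silently repaired — a nearest-positive-definite repair would
quietly move the ground truth that recovery tests assume.

**The study-scale layout** (`default_study_spec`) plants 28 study ROIs
inside a 627-region whole-brain context:

| block | size | internal r | notes |
|---|---|---|---|
| sensory module | 6 | 0.5 (intra) | keys APC, PPC |
| limbic module | 8 | 0.5 | keys AMY, OTB, ENT; hub AMY |
| frontal module | 7 | 0.5 | key Oolf; hub INSa |
| visual control module | 7 | 0.5 | r = 0 to all olfactory ROIs |
| diffuse background | 599 | 0.3 | r = 0.15 to every study ROI |

Between olfactory modules r = `inter` (0.1). Each hub has an elevated
correlation — the midpoint of intra and inter, 0.3 by default — to
every olfactory node outside its own module, which is what makes the
hubs bridge modules, dominate all three centralities, and carry the
largest deletion impacts at generation scale without breaking positive
definiteness.

Two structural choices matter and deserve their rationale:

* *The whole-brain background is first-class.* The per-node
  "top 5% of 625 connections" rule is only selective when each node's
  rank cut is anchored in a large whole-brain context; applied to the
  28 ROIs alone it would retain one edge per node and shred the
  network. Background regions exist to provide that context and the
  global baselines.
* *Background coupling (0.15) exceeds the between-module coupling
  (0.1), and the background's internal level (0.3) exceeds both.* Real
  whole-brain baseline correlations of these ROIs sit above their
  weakest between-module couplings, and anchoring the 5% cut at the
  diffuse background level (~0.15 + noise) is precisely what rejects
  decorrelated regions robustly: after bandpass the effective sample
  of a 4800-scan run is ~480, so pairwise r carries noise of SD ~0.05,
  and a cut anchored at the between-module level would occasionally
  let a zero-correlation control edge through. The ordering
  `background_intra > background_corr` is also a positive-definiteness
  requirement: a 599-node equicorrelated block at level c forces any
  two nodes coupled to it at c to correlate ~c themselves, which would
  contradict the decorrelated control module.

**Motion.** Traces are smooth low-amplitude drifts (sums of slow
sinusoids, ~0.05 mm, plus 0.002 mm jitter) in six parameters; spikes
are persistent translation steps whose sign reinforces the local
baseline increment, so FD at a spike scan is guaranteed ≥ the spike
size, and adjacent spike scans each exceed threshold.

**2AFC observer.** Equal-variance Gaussian signal detection: on a
trial whose dominant odorant has proportion p, the decision variable is
N(±d_eff/2, 1) with d_eff scaled linearly in p (full d′ at 80/20, zero
at 50/50 — the linear scaling is a generator convention, documented
here because the study does not constrain the middle mixtures, which
are excluded from d′ anyway). Hit and false-alarm rates on the extreme
mixtures then recover d′ exactly in expectation.

**Cohorts.** Subject matrices are the group weight pattern plus
independent N(0, 0.12) edge noise; each subject's true d′ is
rank-coupled to their weighted clustering coefficient by converting
clustering ranks to normal scores and mixing Gaussian noise at Pearson
level 2·sin(πρ/6), the level at which a bivariate normal exhibits
Spearman ρ. The study itself gives no generative model linking network
metrics to behavior; this construct exists purely for power and
recovery testing. In the pipeline's validation stage the group weights
are the group |r| matrix itself, so the synthetic "independent sample"
measures the same underlying connectome.

What the generator does **not** emulate: volumetric/voxel-level data
(voxel QC operates on synthetic voxel arrays), physiological noise
(cardiac, respiratory), scanner artifacts, hemispheric signal dropout,
non-Gaussian BOLD amplitude distributions, and genuine inter-subject
anatomical variability. Passing recovery tests therefore show the
*procedures* are correct and well-calibrated under the stated
statistical structure — not that real data meet that structure.

## Preprocessing

Fixed, logged order: per-run mean-centering and whitening →
concatenation → bandpass (per run) → 24-parameter motion regression →
FD scrubbing. Choices where the procedure is conventionally
underdetermined:

* **Filter realization:** order-4 Butterworth applied forward-backward
  (zero phase) per run, after per-run standardization. Whether
  filtering precedes nuisance regression is switchable
  (`bandpass_before_regression`); the listed order is the default.
* **FD rotations** are accepted pre-converted to mm equivalents
  (50-mm-sphere convention), making the 0.5 mm threshold meaningful.
  FD of the first scan of each run is 0 by convention.
* **Scrubbed scans are dropped, not interpolated**, before any
  correlation.
* **Motion regression** uses an intercept plus the 24 regressors;
  rank-deficient designs fall back to the pseudoinverse with a logged
  warning. Residual–regressor correlations are below 1e-10 in tests.
* **Voxel COV masking:** Gaussian-weighted (σ = 5 mm) neighborhood
  mean and SD of the coefficient of variation; a voxel is excluded iff
  its COV exceeds mean + 0.5 SD, with ties (uniform neighborhoods)
  kept and a 1e-12 relative tolerance absorbing roundoff.
* **Participant QC:** exclusion if any ROI has < 50 voxels, > 60% of
  anatomic voxels missing, or ROI SNR (temporal mean / temporal SD —
  the conventional tSNR, since no other definition is fixed by the
  procedure) more than 3 SD below the sample mean for that ROI; the
  olfactory tubercle is exempt from all three rules.

## Network construction

* Fisher z with |r| capped at 1 − 1e-7 (a duplicated-series pair warns
  and caps rather than producing infinities); zero-variance ROIs warn
  and contribute 0.
* The group matrix is the mean of subject Fisher-z matrices.
* The baseline t-test (one-sample, across subjects, of pair z minus
  pair baseline; one-tailed for exceedance) is computed and reported,
  but the operative edge criterion is the top-5% proportional rule on
  the group matrix, matching the practice the construction follows; a
  conjunction mode can be composed by the caller.
* Per-node retention k = floor(density · (N − 1)) — 31 of 625 at 5% —
  and an edge is suprathreshold if marked from **either** endpoint
  (union rule; the AND variant is available). Rank ties break by
  lexicographic node name for determinism.
* Candidates are admitted with ≥ 1 suprathreshold edge to a key seed;
  keys are always retained; roles (key/secondary) annotate the network
  and rejected candidates are reported alongside.

## Graph metrics

* Binary clustering is the triangle fraction; weighted clustering the
  geometric-mean (Onnela) form; weighted distances use edge length
  1/weight — the conventions of the standard brain-connectivity
  toolbox. Weighted metrics reduce exactly to binary ones at unit
  weights.
* Betweenness uses the Brandes fractional-multiplicity convention,
  normalized to a fraction; closeness is the reciprocal of mean
  distance, computed per reachable set with a warning when
  disconnected.
* Louvain keeps the best-Q partition over seeded randomized restarts
  (ties to first occurrence); Girvan–Newman returns the max-Q
  dendrogram level. All reported Q values come from one Newman–Girvan
  modularity function, so Q is consistent with the partition to
  machine precision.
* "Random reassignment of connections" means degree-preserving
  Maslov–Sneppen rewiring (10·E attempted swaps per draw,
  connectedness not enforced); an Erdős–Rényi null with matched n and
  m is available since the wording alone does not exclude it. Each
  null graph is re-partitioned with the same Louvain procedure.
* σ = (C/C_rand)/(L/L_rand), the standard small-world coefficient; G
  and G_rand are reported alongside since efficiency is the quantity
  the analysis emphasizes. Null path lengths average over connected
  pairs so σ stays defined when a rewiring disconnects; complete
  graphs (no swappable pairs) fall back to themselves, giving σ = 1.
* z-rand uses exact first and second moments of the pair count under
  the label-permutation (hypergeometric) null, derived via
  falling-factorial tallies; it matches exhaustive enumeration of all
  permutations on small instances to 1e-10. Degenerate cases
  (single-module partitions) raise rather than return 0/0.
* Node deletion impact is the percentage drop in global efficiency
  after removing the node; efficiency of a disconnected remainder is
  defined (disconnected pairs contribute 0).

## Behavioral linkage

* d′ uses only the extreme mixtures; rates are log-linear corrected
  (add 0.5 to each count, 1 to each denominator) in all cases, which
  keeps 15-trial blocks finite and is asymptotically unbiased (bias
  < 0.05 at 10⁴ trials, verified).
* The permutation Spearman test permutes one variable's midranks
  (vectorized), uses the add-one p-value convention, and is one-tailed
  at the 95th percentile by default (two-tailed by option). Empirical
  type-I error is 0.049 at nominal 0.05 over 2000 null runs.
* Matrix concordance is Spearman over the template-edge entries by
  default (all unique pairs, or Pearson R, by option) — which entries
  enter is a genuine freedom, so it is configurable.

## Problem sizes used by the tests and the acceptance script

Chosen as the package's own balance of statistical resolution against
a desk-scale run: planted-recovery uses the full study conditions
(627 regions, 4 × 1200 scans, intra 0.5 / inter 0.1) over 20 seeds with
50 Louvain restarts and 100-draw modularity nulls per seed; null
calibrations use 200 self-null draws × 50-permutation z-scores and
2000 × 200-permutation Spearman runs; small-world regime checks use
200 rewiring nulls; coupling recovery uses 500 subjects × 500 trials
per mixture (the large-trial readout isolates the coupling from
finite-trial attenuation of d̂′; at the study's own 15 trials the
expected attenuation is ~25%). The acceptance script runs one full
pipeline at study scale with 200 restarts and 500-draw nulls. The
pipeline's own defaults remain the full 10,000
restarts/permutations/rewirings.

## Known limitations

* The t-test against baseline and the top-5% rule are reported side by
  side rather than composed, because their composition is not fixed by
  the procedure being implemented; the default reproduces the
  "top 5% = significant" rule.
* Louvain on binary networks with symmetric near-ties can return
  different equal-Q partitions under different restart seeds;
  downstream consumers should compare partitions by z-rand, not by
  label equality.
* The density sweep compares partitions across densities on the nodes
  admitted at both densities; a node absent at some density appears as
  NaN in the assignment table.
* The synthetic validation cohort shares the template's support
  exactly; real independent samples differ in atlas fit, scanner and
  session length, so real concordance will be far below the synthetic
  value.
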