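"""Synthetic inputs with controllable ground truth.

This module generates everything the real study obtained from scanners and
button boxes: multi-run ROI BOLD timeseries with a planted modular
correlation structure and designated bridging hubs, rigid-body motion
traces with injected spikes, two-alternative forced-choice (2AFC) odor
discrimination trials from an equal-variance Gaussian observer, and
cohorts of subject-level weighted networks coupled to behavior.

The planted correlation structure mirrors the study's situation: a small
set of study ROIs (three interconnected "olfactory" modules plus one
control module standing in for visual cortex) embedded in a large
weakly-correlated whole-brain background that provides the ranking
context for per-node proportional thresholding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .containers import RoiTimeseries

MIXTURES = ("80/20", "60/40", "50/50", "40/60", "20/80")
#: proportion of the dominant odorant in each mixture and which odor dominates
_MIXTURE_DOMINANT = {"80/20": (0.8, "A"), "60/40": (0.6, "A"),
                     "50/50": (0.5, None), "40/60": (0.6, "B"),
                     "20/80": (0.8, "B")}


@dataclass
class GroundTruthSpec:
    """Ground truth for the modular timeseries generator.

    ``module_assignment`` maps every node name to a module label. Pairwise
    correlations are ``intra_module_corr`` within a module and
    ``inter_module_corr`` between modules, with three refinements:

    * ``module_pair_overrides`` replaces the between-module value for
      specific label pairs (e.g. decoupling a control module);
    * ``intra_overrides`` replaces the within-module value for specific
      labels (e.g. an unstructured background block);
    * each node in ``hub_nodes`` gets an elevated correlation
      (``hub_corr``, default the midpoint of intra and inter) to every
      node of the other modules, excluding ``control_modules`` — this is
      what makes the hubs bridge modules and dominate centrality.

    The implied correlation matrix must be positive definite; generation
    fails otherwise rather than silently repairing it.
    """

    module_assignment: dict[str, str]
    intra_module_corr: float = 0.5
    inter_module_corr: float = 0.1
    hub_nodes: tuple[str, ...] = ()
    hub_corr: float | None = None
    control_modules: tuple[str, ...] = ()
    module_pair_overrides: dict[frozenset, float] = field(default_factory=dict)
    intra_overrides: dict[str, float] = field(default_factory=dict)
    n_runs: int = 4
    scans_per_run: int = 1200
    repetition_time: float = 0.72
    ar_coeff: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.inter_module_corr < 1 or not 0 <= self.intra_module_corr < 1:
            raise ValueError("correlations must lie in [0, 1)")
        if not self.intra_module_corr > self.inter_module_corr:
            raise ValueError("intra_module_corr must exceed inter_module_corr")
        if self.hub_corr is None:
            self.hub_corr = 0.5 * (self.intra_module_corr + self.inter_module_corr)
        missing = set(self.hub_nodes) - set(self.module_assignment)
        if missing:
            raise ValueError(f"hub_nodes not in module_assignment: {sorted(missing)}")
        if self.n_runs < 1 or self.scans_per_run < 1:
            raise ValueError("n_runs and scans_per_run must be positive")
        if not self.repetition_time > 0:
            raise ValueError("repetition_time must be positive")
        if not 0 <= self.ar_coeff < 1:
            raise ValueError("ar_coeff must lie in [0, 1)")

    @property
    def node_names(self) -> list[str]:
        return list(self.module_assignment)

    @property
    def n_nodes(self) -> int:
        return len(self.module_assignment)

    def module_labels(self, nodes=None) -> np.ndarray:
        nodes = self.node_names if nodes is None else nodes
        return np.array([self.module_assignment[n] for n in nodes])


def build_correlation_matrix(spec: GroundTruthSpec) -> np.ndarray:
    """Assemble the planted correlation matrix implied by *spec*.

    Raises ``ValueError`` naming the offending parameters if the implied
    matrix is not positive definite.
    """
    names = spec.node_names
    mods = spec.module_labels()
    n = spec.n_nodes
    r = np.full((n, n), spec.inter_module_corr)
    for pair, val in spec.module_pair_overrides.items():
        pair = frozenset(pair)
        if len(pair) == 1:
            (a,) = pair
            b = a
        else:
            a, b = pair
        ia, ib = mods == a, mods == b
        r[np.ix_(ia, ib)] = val
        r[np.ix_(ib, ia)] = val
    same = mods[:, None] == mods[None, :]
    r[same] = spec.intra_module_corr
    for label, val in spec.intra_overrides.items():
        block = (mods == label)[:, None] & (mods == label)[None, :]
        r[block] = val
    hub_targets = ~np.isin(mods, spec.control_modules)
    for hub in spec.hub_nodes:
        i = names.index(hub)
        cross = hub_targets & (mods != mods[i])
        r[i, cross] = spec.hub_corr
        r[cross, i] = spec.hub_corr
    np.fill_diagonal(r, 1.0)
    try:
        np.linalg.cholesky(r)
    except np.linalg.LinAlgError:
        raise ValueError(
            "implied correlation matrix is not positive definite "
            f"(intra={spec.intra_module_corr}, inter={spec.inter_module_corr}, "
            f"hub_corr={spec.hub_corr}, overrides={spec.module_pair_overrides})"
        ) from None
    return r


def generate_modular_timeseries(spec: GroundTruthSpec) -> RoiTimeseries:
    """Draw multi-run Gaussian node signals with the planted correlation.

    Signals are zero-mean unit-variance Gaussian, temporally white by
    default; ``spec.ar_coeff`` > 0 applies an AR(1) recursion to each
    node (same coefficient everywhere, so cross-node correlations are
    preserved) to give the bandpass stage band-limited content to work
    on. Deterministic given ``spec.seed``.
    """
    r = build_correlation_matrix(spec)
    chol = np.linalg.cholesky(r)
    rng = np.random.default_rng(spec.seed)
    runs = []
    for _ in range(spec.n_runs):
        z = rng.standard_normal((spec.scans_per_run, spec.n_nodes))
        if spec.ar_coeff > 0:
            phi = spec.ar_coeff
            for t in range(1, z.shape[0]):
                z[t] = phi * z[t - 1] + np.sqrt(1 - phi * phi) * z[t]
        runs.append(z @ chol.T)
    values = np.vstack(runs)
    run_ids = np.repeat(np.arange(spec.n_runs), spec.scans_per_run)
    return RoiTimeseries(values=values, roi_names=spec.node_names,
                         run_ids=run_ids, tr=spec.repetition_time)


def inject_motion(n_scans: int, spike_scans=(), spike_size: float = 1.0,
                  seed: int = 0, baseline_amplitude: float = 0.05,
                  noise_sd: float = 0.002) -> np.ndarray:
    """Six-parameter rigid-body motion trace with translation spikes.

    Returns an ``(n_scans, 6)`` array: three translations (mm) and three
    rotations (already expressed in mm-equivalent units, 50-mm-sphere
    convention). The baseline is a smooth low-amplitude drift; at each
    scan in ``spike_scans`` a persistent translation step of
    ``spike_size`` mm is added, signed to reinforce the local baseline
    increment so the framewise displacement at that scan is at least
    ``spike_size``.
    """
    spike_scans = sorted(set(int(s) for s in spike_scans))
    if spike_scans and (spike_scans[0] < 0 or spike_scans[-1] >= n_scans):
        raise IndexError(f"spike scan out of range [0, {n_scans})")
    rng = np.random.default_rng(seed)
    t = np.arange(n_scans)[:, None]
    freq = rng.uniform(0.001, 0.004, size=6)
    phase = rng.uniform(0, 2 * np.pi, size=6)
    motion = baseline_amplitude * np.sin(2 * np.pi * freq * t + phase)
    motion += noise_sd * rng.standard_normal((n_scans, 6))
    for s in spike_scans:
        delta = motion[s, 0] - motion[s - 1, 0] if s > 0 else 0.0
        sign = 1.0 if delta >= 0 else -1.0
        motion[s:, 0] += sign * spike_size
    return motion


def generate_2afc_trials(true_dprime: float, trials_per_mixture: int = 15,
                         seed: int = 0) -> pd.DataFrame:
    """Simulate 2AFC responses over five binary odor mixtures.

    The observer follows the equal-variance Gaussian model: on a trial of
    a mixture whose dominant odorant has proportion ``p``, the decision
    variable is N(+-d_eff/2, 1) with the sign set by the true dominant
    odor and an effective sensitivity scaled linearly in ``p``
    (d_eff = true_dprime at 80/20, 0 at 50/50). Responses to the extreme
    mixtures therefore recover ``true_dprime`` as Z(hit) - Z(false alarm).

    Returns a DataFrame with columns ``mixture``, ``truth``, ``response``.
    """
    if trials_per_mixture < 1:
        raise ValueError("trials_per_mixture must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for mixture in MIXTURES:
        p_dom, dominant = _MIXTURE_DOMINANT[mixture]
        d_eff = true_dprime * (p_dom - 0.5) / 0.3
        for k in range(trials_per_mixture):
            truth = dominant if dominant is not None else ("A" if k % 2 == 0 else "B")
            mu = d_eff / 2 if truth == "A" else -d_eff / 2
            response = "A" if rng.normal(mu, 1.0) > 0 else "B"
            rows.append((mixture, truth, response))
    return pd.DataFrame(rows, columns=["mixture", "truth", "response"])


def write_trials_csv(trials: pd.DataFrame, path) -> None:
    trials.to_csv(path, index=False)


def read_trials_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    expected = {"mixture", "truth", "response"}
    if not expected.issubset(df.columns):
        raise ValueError(f"{path}: trials CSV must have columns {sorted(expected)}")
    return df


# ---------------------------------------------------------------------------
# Default study layout: 28 study ROIs in a whole-brain context
# ---------------------------------------------------------------------------

#: the three planted olfactory modules; asterisk-free key regions are the
#: six seed ROIs, AMY and INSa are the planted bridging hubs
STUDY_MODULES = {
    "sensory": ("APC", "PPC", "INSv", "INSd", "INSp", "THLvp"),
    "limbic": ("AMY", "OTB", "ENT", "aHIP", "pHIP", "HYP", "NAcc", "Omm"),
    "frontal": ("Oolf", "INSa", "Oc", "Opm", "Oml", "Opl", "Omp"),
    "visual": ("Cal1", "Cal2", "Cun1", "Cun2", "OccI1", "OccM1", "OccS1"),
}
KEY_NODES = ("APC", "PPC", "AMY", "ENT", "OTB", "Oolf")
HUB_NODES = ("AMY", "INSa")
OLFACTORY_MODULES = ("sensory", "limbic", "frontal")


def study_roi_names() -> list[str]:
    return [n for nodes in STUDY_MODULES.values() for n in nodes]


def default_study_spec(seed: int = 0, n_background: int = 599,
                       intra: float = 0.5, inter: float = 0.1,
                       background_corr: float = 0.15,
                       background_intra: float = 0.3,
                       n_runs: int = 4, scans_per_run: int = 1200,
                       repetition_time: float = 0.72,
                       ar_coeff: float = 0.0) -> GroundTruthSpec:
    """The study-scale ground truth: 28 ROIs in a 627-region context.

    Three olfactory modules (sensory 6, limbic 8, frontal 7 nodes) carry
    the six key seed regions and two bridging hubs; a 7-node control
    ("visual") module is internally coherent but decorrelated from the
    olfactory ROIs; the remaining background regions form a diffuse
    block (internal correlation ``background_intra``) coupled at
    ``background_corr`` to every study ROI, providing the whole-brain
    ranking context for proportional thresholding and global baselines.
    ``background_corr`` defaults above ``inter``, mirroring real
    whole-brain baselines that sit above the weakest between-module ROI
    couplings; this anchors each node's proportional-threshold cut to
    the diffuse background rather than to noise on decorrelated pairs,
    which is what makes the top-few-percent rule selective.
    ``background_intra`` must exceed ``background_corr`` for the implied
    matrix to stay positive definite alongside the decorrelated control
    module.
    """
    assignment: dict[str, str] = {}
    for label, nodes in STUDY_MODULES.items():
        for node in nodes:
            assignment[node] = label
    for k in range(n_background):
        assignment[f"Bg{k:03d}"] = "background"
    return GroundTruthSpec(
        module_assignment=assignment,
        intra_module_corr=intra,
        inter_module_corr=inter,
        hub_nodes=HUB_NODES,
        control_modules=("visual", "background"),
        module_pair_overrides={
            frozenset(("visual", "sensory")): 0.0,
            frozenset(("visual", "limbic")): 0.0,
            frozenset(("visual", "frontal")): 0.0,
            frozenset(("visual", "background")): background_corr,
            frozenset(("background", "sensory")): background_corr,
            frozenset(("background", "limbic")): background_corr,
            frozenset(("background", "frontal")): background_corr,
        },
        intra_overrides={"background": background_intra},
        n_runs=n_runs,
        scans_per_run=scans_per_run,
        repetition_time=repetition_time,
        ar_coeff=ar_coeff,
        seed=seed,
    )


def planted_secondary_nodes() -> list[str]:
    """Candidates that ground truth says belong to the olfactory network."""
    keys = set(KEY_NODES)
    return [n for m in OLFACTORY_MODULES for n in STUDY_MODULES[m] if n not in keys]


# ---------------------------------------------------------------------------
# Cohorts of subject-level weighted networks with behavioral coupling
# ---------------------------------------------------------------------------

@dataclass
class SubjectRecord:
    """One synthetic subject: correlation matrix, trials, and true d'."""

    matrix: "ConnectivityMatrix"
    trials: pd.DataFrame
    true_dprime: float


@dataclass
class Cohort:
    subjects: list[SubjectRecord]
    template: "BinaryNetwork"

    def __len__(self) -> int:
        return len(self.subjects)


def generate_cohort(n_subjects: int, template, behavior_coupling_rho: float,
                    seed: int = 0, template_weights: np.ndarray | None = None,
                    subject_noise_sd: float = 0.12,
                    trials_per_mixture: int = 15,
                    dprime_mean: float = 1.5,
                    dprime_sd: float = 0.5) -> Cohort:
    """Generate subject-level (matrix, trials) pairs sharing a template.

    Each subject's correlation matrix is the template-consistent group
    weight pattern plus independent subject noise; each subject's true d'
    is generated so the population Spearman correlation between weighted
    clustering (of the template-masked network) and true d' approaches
    ``behavior_coupling_rho``. The planting converts clustering ranks to
    normal scores and mixes in independent Gaussian noise at the Pearson
    correlation 2*sin(pi*rho/6) that a bivariate normal needs to exhibit
    Spearman rho.
    """
    from .behavior import mask_subject_network
    from .containers import ConnectivityMatrix
    from .graphmetrics import clustering_coefficient

    if not -1 <= behavior_coupling_rho <= 1:
        raise ValueError("|behavior_coupling_rho| must be <= 1")
    if template.n_edges == 0:
        raise ValueError("degenerate template: no edges")
    rng = np.random.default_rng(seed)
    n = template.n_nodes
    if template_weights is None:
        upper = np.triu(rng.uniform(0.3, 0.8, size=(n, n)), 1)
        template_weights = (upper + upper.T) * template.adjacency
    base = np.where(template.adjacency > 0, template_weights, 0.05)
    np.fill_diagonal(base, 0.0)

    matrices, cws = [], []
    for _ in range(n_subjects):
        noise = np.triu(rng.normal(0.0, subject_noise_sd, size=(n, n)), 1)
        r = np.clip(base + noise + noise.T, -0.99, 0.99)
        np.fill_diagonal(r, 0.0)
        mat = ConnectivityMatrix(list(template.node_names), np.arctanh(r))
        matrices.append(mat)
        cws.append(clustering_coefficient(
            mask_subject_network(mat, template), weighted=True))

    # rank-couple true d' to weighted clustering at the requested Spearman rho
    pearson_r = 2 * np.sin(np.pi * behavior_coupling_rho / 6)
    ranks = stats.rankdata(cws)
    zc = stats.norm.ppf(ranks / (n_subjects + 1))
    latent = pearson_r * zc + np.sqrt(1 - pearson_r ** 2) * rng.standard_normal(n_subjects)
    true_d = np.maximum(dprime_mean + dprime_sd * latent, 0.05)

    subjects = []
    for i in range(n_subjects):
        trials = generate_2afc_trials(float(true_d[i]), trials_per_mixture,
                                      seed=int(rng.integers(2 ** 31 - 1)))
        subjects.append(SubjectRecord(matrices[i], trials, float(true_d[i])))
    if n_subjects == 1:
        warnings.warn("single-subject cohort: downstream correlations undefined")
    return Cohort(subjects=subjects, template=template)
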