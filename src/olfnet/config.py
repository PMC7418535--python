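"""Structured pipeline configuration.

Every threshold the analysis applies lives here with its default
(0.5 mm FD, 0.01/0.08 Hz bandpass, 5% connection density, 0.04-0.10
density grid, Q cutoff 0.3, modularity Z cutoff 3, 10,000 permutations),
so a single resolved YAML file documents a run completely. Unknown keys
are rejected; every pipeline run writes a resolved copy of its config
next to its outputs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml


def _from_dict(cls, data: dict, context: str):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config key(s) under '{context}': {sorted(unknown)}")
    kwargs = {}
    for f in fields(cls):
        if f.name not in data:
            continue
        val = data[f.name]
        if cls is _SECTIONS.get("__root__") and f.name in _SECTIONS:
            val = _from_dict(_SECTIONS[f.name], val, f"{context}.{f.name}")
        kwargs[f.name] = val
    return cls(**kwargs)


@dataclass
class SimulateConfig:
    n_background: int = 599
    intra_corr: float = 0.5
    inter_corr: float = 0.1
    n_runs: int = 4
    scans_per_run: int = 1200
    repetition_time: float = 0.72
    ar_coeff: float = 0.0
    spike_fraction: float = 0.01
    spike_size_mm: float = 1.0


@dataclass
class PreprocessConfig:
    fd_threshold_mm: float = 0.5
    bandpass_low_hz: float = 0.01
    bandpass_high_hz: float = 0.08
    filter_order: int = 4
    bandpass_before_regression: bool = True
    cov_sigma_mm: float = 5.0
    cov_cutoff_sd: float = 0.5
    qc_min_voxels: int = 50
    qc_max_missing_fraction: float = 0.6
    qc_snr_sd: float = 3.0


@dataclass
class NetbuildConfig:
    density: float = 0.05
    density_grid: list = field(
        default_factory=lambda: [float(round(d, 3)) for d in np.arange(0.04, 0.1001, 0.005)])
    threshold_rule: str = "union"
    control_densities: list = field(default_factory=lambda: [0.05, 0.10, 0.15])


@dataclass
class GraphConfig:
    n_restarts: int = 10000
    n_perm: int = 10000
    n_rand: int = 10000
    null_model: str = "degree_preserving"
    q_cutoff: float = 0.3
    z_cutoff: float = 3.0


@dataclass
class BehaviorConfig:
    n_subjects: int = 32
    coupling_rho: float = 0.4
    trials_per_mixture: int = 15
    n_perm: int = 10000


@dataclass
class StagesConfig:
    simulate: bool = True
    preprocess: bool = True
    netbuild: bool = True
    graph: bool = True
    behavior: bool = True


@dataclass
class PipelineConfig:
    seed: int = 0
    write_timeseries: bool = False
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    netbuild: NetbuildConfig = field(default_factory=NetbuildConfig)
    graph: GraphConfig = field(default_factory=GraphConfig)
    behavior: BehaviorConfig = field(default_factory=BehaviorConfig)
    stages: StagesConfig = field(default_factory=StagesConfig)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        return _from_dict(cls, data or {}, "pipeline")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


#: nested sections of PipelineConfig; __root__ marks the only level at
#: which section names trigger recursion (StagesConfig reuses the same
#: names for its boolean toggles)
_SECTIONS = {
    "__root__": PipelineConfig,
    "simulate": SimulateConfig,
    "preprocess": PreprocessConfig,
    "netbuild": NetbuildConfig,
    "graph": GraphConfig,
    "behavior": BehaviorConfig,
    "stages": StagesConfig,
}
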