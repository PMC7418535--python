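"""Core in-memory containers shared across the pipeline stages.

The pipeline's raw input is an :class:`RoiTimeseries` (scans x ROI BOLD
matrix with run labels and a retention mask), which flows through
preprocessing into a Fisher-z :class:`ConnectivityMatrix`, a thresholded
:class:`BinaryNetwork`, and per-node/partition summaries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

SYMMETRY_TOL = 1e-12


@dataclass
class RoiTimeseries:
    """Multi-run ROI-averaged BOLD timeseries.

    Parameters
    ----------
    values : ndarray, shape (n_scans, n_rois)
        BOLD values in arbitrary units; rows are scans (all runs
        concatenated in acquisition order), columns are ROIs.
    roi_names : list of str
        Unique, ordered ROI labels matching the columns.
    run_ids : ndarray of int, shape (n_scans,)
        Run label per scan; scans of a run are contiguous.
    tr : float
        Repetition time in seconds.
    scan_mask : ndarray of bool, shape (n_scans,)
        True for retained scans; scrubbing clears entries.
    """

    values: np.ndarray
    roi_names: list[str]
    run_ids: np.ndarray
    tr: float
    scan_mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D scans x ROI matrix")
        self.run_ids = np.asarray(self.run_ids, dtype=int)
        if self.run_ids.shape != (self.values.shape[0],):
            raise ValueError("run_ids must have one entry per scan")
        if self.scan_mask is None:
            self.scan_mask = np.ones(self.values.shape[0], dtype=bool)
        self.scan_mask = np.asarray(self.scan_mask, dtype=bool)
        if self.scan_mask.shape != (self.values.shape[0],):
            raise ValueError("scan_mask must have one entry per scan")
        if len(self.roi_names) != self.values.shape[1]:
            raise ValueError("roi_names must match the number of columns")
        if len(set(self.roi_names)) != len(self.roi_names):
            raise ValueError("roi_names must be unique")
        if not self.tr > 0:
            raise ValueError("repetition_time must be positive")
        if not np.isfinite(self.values[self.scan_mask]).all():
            raise ValueError("retained scans contain non-finite values")

    @property
    def n_scans(self) -> int:
        return self.values.shape[0]

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]

    @property
    def n_retained(self) -> int:
        return int(self.scan_mask.sum())

    def retained_values(self) -> np.ndarray:
        return self.values[self.scan_mask]

    def iter_runs(self):
        """Yield ``(run_id, row_indices)`` for each run in order."""
        for run in pd.unique(self.run_ids):
            yield int(run), np.flatnonzero(self.run_ids == run)

    def copy_with(self, values: np.ndarray | None = None,
                  scan_mask: np.ndarray | None = None) -> "RoiTimeseries":
        return RoiTimeseries(
            values=self.values.copy() if values is None else values,
            roi_names=list(self.roi_names),
            run_ids=self.run_ids.copy(),
            tr=self.tr,
            scan_mask=self.scan_mask.copy() if scan_mask is None else scan_mask,
        )

    def to_tsv(self, path: str | Path) -> None:
        """Write as TSV: ``run`` column then one column per ROI, one row per scan."""
        df = pd.DataFrame(self.values, columns=self.roi_names)
        df.insert(0, "run", self.run_ids)
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, tr: float) -> "RoiTimeseries":
        df = pd.read_csv(path, sep="\t")
        if "run" not in df.columns:
            raise ValueError(f"{path}: missing 'run' column")
        run_ids = df.pop("run").to_numpy()
        return cls(values=df.to_numpy(float), roi_names=list(df.columns),
                   run_ids=run_ids, tr=tr)


@dataclass
class FdSeries:
    """Per-scan framewise displacement (mm) with the scrubbing threshold."""

    values: np.ndarray
    threshold: float = 0.5

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if (self.values < 0).any():
            raise ValueError("framewise displacement must be non-negative")

    @property
    def spikes(self) -> np.ndarray:
        """Boolean mask of scans whose FD exceeds the threshold."""
        return self.values > self.threshold


@dataclass
class VoxelRoi:
    """Voxel-level view of one ROI for coefficient-of-variation QC.

    ``coords`` are voxel centers in mm; ``cov`` is each voxel's temporal
    coefficient of variation (SD/mean, dimensionless).
    """

    coords: np.ndarray
    cov: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        self.cov = np.asarray(self.cov, dtype=float)
        if self.coords.shape[1] != 3:
            raise ValueError("coords must be (n_voxels, 3) in mm")
        if self.cov.shape != (self.coords.shape[0],):
            raise ValueError("one COV value per voxel required")
        if not np.isfinite(self.coords).all():
            raise ValueError("voxel coordinates must be finite")
        if (self.cov < 0).any():
            raise ValueError("COV must be non-negative")


@dataclass
class ConnectivityMatrix:
    """Symmetric ROI x ROI Fisher-z connectivity matrix.

    The diagonal is undefined and stored as zero; ``level`` marks whether
    the matrix is subject-level or a group aggregate.
    """

    node_names: list[str]
    values: np.ndarray
    level: str = "subject"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.node_names)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape must match node_names")
        if len(set(self.node_names)) != n:
            raise ValueError("node_names must be unique")
        if not np.allclose(self.values, self.values.T, atol=SYMMETRY_TOL):
            raise ValueError("connectivity matrix must be symmetric")
        off = self.values[~np.eye(n, dtype=bool)]
        if not np.isfinite(off).all():
            raise ValueError("off-diagonal entries must be finite")
        np.fill_diagonal(self.values, 0.0)
        if self.level not in ("subject", "group"):
            raise ValueError("level must be 'subject' or 'group'")

    @property
    def n_nodes(self) -> int:
        return len(self.node_names)

    def index_of(self, names) -> np.ndarray:
        lookup = {n: i for i, n in enumerate(self.node_names)}
        missing = [n for n in names if n not in lookup]
        if missing:
            raise KeyError(f"nodes absent from matrix: {missing}")
        return np.array([lookup[n] for n in names], dtype=int)

    def submatrix(self, names) -> "ConnectivityMatrix":
        idx = self.index_of(names)
        return ConnectivityMatrix(list(names), self.values[np.ix_(idx, idx)],
                                  level=self.level)

    def to_r(self) -> np.ndarray:
        """Back-transform Fisher z to Pearson r (diagonal left at 0)."""
        return np.tanh(self.values)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.node_names,
                     columns=self.node_names).to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path, level: str = "subject") -> "ConnectivityMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(list(df.columns), df.to_numpy(float), level=level)


@dataclass
class BinaryNetwork:
    """Symmetric 0/1 adjacency over named nodes, no self-loops.

    ``roles`` optionally annotates nodes as ``key`` (seed olfactory
    region), ``secondary`` (admitted candidate) or ``rejected``.
    """

    node_names: list[str]
    adjacency: np.ndarray
    roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency)
        n = len(self.node_names)
        if self.adjacency.shape != (n, n):
            raise ValueError("adjacency shape must match node_names")
        if not np.array_equal(self.adjacency, self.adjacency.T):
            raise ValueError("adjacency must be symmetric")
        if not np.isin(self.adjacency, (0, 1)).all():
            raise ValueError("adjacency must be 0/1")
        self.adjacency = self.adjacency.astype(np.int8)
        np.fill_diagonal(self.adjacency, 0)
        unknown = set(self.roles) - set(self.node_names)
        if unknown:
            raise ValueError(f"roles refer to unknown nodes: {sorted(unknown)}")

    @property
    def n_nodes(self) -> int:
        return len(self.node_names)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def degree(self) -> np.ndarray:
        return self.adjacency.sum(axis=0).astype(int)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.node_names)
        ii, jj = np.nonzero(np.triu(self.adjacency, 1))
        g.add_edges_from((self.node_names[i], self.node_names[j])
                         for i, j in zip(ii, jj))
        return g

    def subnetwork(self, names) -> "BinaryNetwork":
        lookup = {n: i for i, n in enumerate(self.node_names)}
        idx = np.array([lookup[n] for n in names], dtype=int)
        roles = {n: r for n, r in self.roles.items() if n in set(names)}
        return BinaryNetwork(list(names), self.adjacency[np.ix_(idx, idx)], roles)

    def to_edgelist_tsv(self, path: str | Path,
                        weights: np.ndarray | None = None) -> None:
        ii, jj = np.nonzero(np.triu(self.adjacency, 1))
        rows = [(self.node_names[i], self.node_names[j],
                 1.0 if weights is None else float(weights[i, j]))
                for i, j in zip(ii, jj)]
        pd.DataFrame(rows, columns=["node_a", "node_b", "weight"]).to_csv(
            path, sep="\t", index=False)

    def to_json(self, path: str | Path) -> None:
        ii, jj = np.nonzero(np.triu(self.adjacency, 1))
        payload = {
            "nodes": self.node_names,
            "roles": self.roles,
            "edges": [[self.node_names[i], self.node_names[j]]
                      for i, j in zip(ii, jj)],
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_edgelist_tsv(cls, path: str | Path,
                          node_names=None) -> "BinaryNetwork":
        """Read a 3-column (node_a, node_b, weight) TSV; any nonzero
        weight is an edge. Isolated nodes survive only if listed in
        ``node_names``."""
        df = pd.read_csv(path, sep="\t")
        required = {"node_a", "node_b", "weight"}
        if not required.issubset(df.columns):
            raise ValueError(f"{path}: edge list must have columns "
                             f"{sorted(required)}")
        if node_names is None:
            node_names = sorted(set(df["node_a"]) | set(df["node_b"]))
        lookup = {n: i for i, n in enumerate(node_names)}
        adj = np.zeros((len(node_names), len(node_names)), dtype=np.int8)
        for _, row in df.iterrows():
            if row["weight"] != 0:
                i, j = lookup[row["node_a"]], lookup[row["node_b"]]
                adj[i, j] = adj[j, i] = 1
        return cls(list(node_names), adj)

    @classmethod
    def from_json(cls, path: str | Path) -> "BinaryNetwork":
        payload = json.loads(Path(path).read_text())
        names = payload["nodes"]
        lookup = {n: i for i, n in enumerate(names)}
        adj = np.zeros((len(names), len(names)), dtype=np.int8)
        for a, b in payload["edges"]:
            adj[lookup[a], lookup[b]] = adj[lookup[b], lookup[a]] = 1
        return cls(names, adj, payload.get("roles", {}))


@dataclass
class Partition:
    """Node -> module assignment with its modularity score.

    ``labels`` maps node name to an integer module id; ``q`` is the
    Newman-Girvan modularity of this partition on the network it was
    computed from; ``zscore`` (optional) is Q standardized against a
    rewiring null distribution.
    """

    labels: dict[str, int]
    q: float
    algorithm: str = ""
    zscore: float | None = None

    def __post_init__(self) -> None:
        if not -0.5 - 1e-9 <= self.q <= 1.0 + 1e-9:
            raise ValueError(f"modularity Q out of range [-1/2, 1]: {self.q}")

    @property
    def n_modules(self) -> int:
        return len(set(self.labels.values()))

    def membership(self, node_order) -> np.ndarray:
        return np.array([self.labels[n] for n in node_order], dtype=int)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "labels": self.labels, "q": self.q,
            "algorithm": self.algorithm, "zscore": self.zscore,
            "n_modules": self.n_modules}, indent=2))
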