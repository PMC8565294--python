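"""Functional-connectivity construction and sparsity thresholding.

From ROI time series to a Fisher-z correlation matrix, then to binary
undirected graphs across a band of network sparsities.  Thresholding is
by sparsity (fraction of possible edges kept) rather than by correlation
value, so every subject's graph has the same edge count at a given grid
point; only positive correlations are eligible to become edges.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .synthetic import ROITimeSeriesSet

__all__ = [
    "FCMatrix",
    "ThresholdGrid",
    "BinaryGraph",
    "ConnectednessReport",
    "compute_fc_matrix",
    "binarize_at_sparsity",
    "check_connectedness_floor",
    "read_timeseries_tsv",
    "write_fc_tsv",
    "read_fc_tsv",
    "write_edge_list",
]

#: correlation magnitudes are clipped here so atanh stays finite
R_CLIP = 1.0 - 1e-7


@dataclass(frozen=True)
class FCMatrix:
    """Symmetric N x N Fisher-z connectivity matrix, zero diagonal."""

    z: np.ndarray
    n_timepoints: int
    subject_id: str = ""

    def __post_init__(self):
        z = np.asarray(self.z, dtype=float)
        object.__setattr__(self, "z", z)
        if z.ndim != 2 or z.shape[0] != z.shape[1]:
            raise ValueError("z must be square")
        if not np.allclose(z, z.T):
            raise ValueError("z must be symmetric")
        if not np.all(np.isfinite(z)):
            raise ValueError("z must be finite everywhere")
        if np.any(np.diagonal(z) != 0):
            raise ValueError("diagonal must be exactly 0")

    @property
    def n_nodes(self) -> int:
        return self.z.shape[0]


@dataclass(frozen=True)
class ThresholdGrid:
    """Strictly increasing sparsity values in (0, 0.5]."""

    sparsities: tuple[float, ...] = field(
        default_factory=lambda: tuple(np.round(np.arange(1, 9) * 0.05, 10)))

    def __post_init__(self):
        s = tuple(float(v) for v in self.sparsities)
        object.__setattr__(self, "sparsities", s)
        if len(s) < 1:
            raise ValueError("grid must be non-empty")
        if any(not (0 < v <= 0.5) for v in s):
            raise ValueError("sparsities must lie in (0, 0.5]")
        if any(b <= a for a, b in zip(s, s[1:])):
            raise ValueError("sparsities must be strictly increasing")

    @classmethod
    def from_range(cls, start: float = 0.05, stop: float = 0.40,
                   step: float = 0.05) -> "ThresholdGrid":
        n = (stop - start) / step
        if abs(n - round(n)) > 1e-6:
            raise ValueError("step must divide (stop - start)")
        pts = start + step * np.arange(round(n) + 1)
        return cls(tuple(np.round(pts, 10)))

    def __len__(self) -> int:
        return len(self.sparsities)

    def __iter__(self):
        return iter(self.sparsities)


@dataclass(frozen=True)
class BinaryGraph:
    """Undirected unweighted graph at one sparsity point."""

    adjacency: np.ndarray
    sparsity: float = 0.0
    truncated: bool = False  # fewer positive entries than the target count

    def __post_init__(self):
        adj = np.ascontiguousarray(np.asarray(self.adjacency), dtype=np.uint8)
        object.__setattr__(self, "adjacency", adj)
        if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(adj, adj.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diagonal(adj) != 0):
            raise ValueError("self-loops are not allowed")
        if not np.all((adj == 0) | (adj == 1)):
            raise ValueError("adjacency must be 0/1")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(np.int64)

    def edge_list(self) -> np.ndarray:
        """E x 2 array of edges (i < j), lexicographic order."""
        iu = np.triu_indices(self.n_nodes, 1)
        mask = self.adjacency[iu] != 0
        return np.column_stack([iu[0][mask], iu[1][mask]])


@dataclass(frozen=True)
class ConnectednessReport:
    mean_degree: float
    log_n: float
    mean_degree_exceeds_log_n: bool
    n_components: int


def compute_fc_matrix(ts: ROITimeSeriesSet) -> FCMatrix:
    """Pearson correlation of every node pair, Fisher r-to-z transformed.

    Correlations are clipped into [-1 + 1e-7, 1 - 1e-7] before atanh so
    duplicated signals stay finite; the diagonal is set to 0.
    """
    data = ts.data
    sd = data.std(axis=0)
    if np.any(sd == 0):
        bad = int(np.flatnonzero(sd == 0)[0])
        raise ValueError(
            f"subject {ts.subject_id}: node {ts.node_ids[bad]} has zero "
            "variance; cannot correlate")
    r = np.corrcoef(data, rowvar=False)
    z = np.arctanh(np.clip(r, -R_CLIP, R_CLIP))
    z = (z + z.T) / 2.0
    np.fill_diagonal(z, 0.0)
    return FCMatrix(z=z, n_timepoints=ts.n_timepoints,
                    subject_id=ts.subject_id)


def target_edge_count(s: float, n_nodes: int) -> int:
    """Edge count at sparsity s: round(s * N(N-1)/2), half away from zero."""
    x = s * n_nodes * (n_nodes - 1) / 2.0
    return int(math.floor(x + 0.5))


def binarize_at_sparsity(fc: FCMatrix, s: float) -> BinaryGraph:
    """Keep the E(s) strongest strictly positive connections as edges.

    Ties in z are broken by ascending (i, j) lexicographic order.  If the
    matrix holds fewer positive entries than E(s), all positive entries
    become edges and a warning is issued (the graph is flagged
    ``truncated``).  A matrix with no positive entries is an error.
    """
    if not (0 < s <= 0.5):
        raise ValueError("sparsity must be in (0, 0.5]")
    n = fc.n_nodes
    target = target_edge_count(s, n)
    iu, ju = np.triu_indices(n, 1)
    vals = fc.z[iu, ju]
    pos = vals > 0
    n_pos = int(pos.sum())
    if n_pos == 0:
        raise ValueError("no positive connections: empty graph is not "
                         "analyzable")
    truncated = n_pos < target
    if truncated:
        warnings.warn(
            f"only {n_pos} positive connections available for target "
            f"{target} at sparsity {s}; using all of them", stacklevel=2)
    pi, pj, pv = iu[pos], ju[pos], vals[pos]
    order = np.lexsort((pj, pi, -pv))
    keep = order[:min(target, n_pos)]
    adj = np.zeros((n, n), dtype=np.uint8)
    adj[pi[keep], pj[keep]] = 1
    adj[pj[keep], pi[keep]] = 1
    return BinaryGraph(adjacency=adj, sparsity=s, truncated=truncated)


def check_connectedness_floor(g: BinaryGraph) -> ConnectednessReport:
    """Mean degree vs. ln(N) sanity floor plus a component count (BFS)."""
    n = g.n_nodes
    mean_degree = float(g.degrees().mean())
    log_n = float(np.log(n))
    n_comp, _ = connected_components(csr_matrix(g.adjacency),
                                     directed=False)
    return ConnectednessReport(
        mean_degree=mean_degree,
        log_n=log_n,
        mean_degree_exceeds_log_n=mean_degree > log_n,
        n_components=int(n_comp),
    )


# ---------------------------------------------------------------------------
# Text I/O

def read_timeseries_tsv(path, subject_id: str | None = None,
                        node_ids=None) -> ROITimeSeriesSet:
    path = Path(path)
    data = np.loadtxt(path, delimiter="\t", ndmin=2)
    if subject_id is None:
        subject_id = path.stem.replace("_timeseries", "")
    if node_ids is None:
        node_ids = tuple(range(data.shape[1]))
    return ROITimeSeriesSet(subject_id, data, tuple(node_ids))


def write_fc_tsv(fc: FCMatrix, path) -> None:
    np.savetxt(path, fc.z, delimiter="\t", fmt="%.8f")


def read_fc_tsv(path, n_timepoints: int = 0,
                subject_id: str = "") -> FCMatrix:
    z = np.loadtxt(path, delimiter="\t", ndmin=2)
    z = (z + z.T) / 2.0
    np.fill_diagonal(z, 0.0)
    return FCMatrix(z=z, n_timepoints=n_timepoints, subject_id=subject_id)


def write_edge_list(g: BinaryGraph, path) -> None:
    """Edge list (`i<TAB>j`, i < j, 0-based) preceded by a JSON header
    line carrying N, sparsity and the edge count."""
    header = json.dumps({"n_nodes": g.n_nodes, "sparsity": g.sparsity,
                         "n_edges": g.n_edges})
    edges = g.edge_list()
    with open(path, "w") as fh:
        fh.write(f"# {header}\n")
        for i, j in edges:
            fh.write(f"{i}\t{j}\n")


def load_cohort_dir(directory):
    """Read every `*_timeseries.tsv` in a cohort directory plus the
    clinical table.  Returns (list of ROITimeSeriesSet, clinical frame)."""
    directory = Path(directory)
    clin_path = directory / "clinical.csv"
    if not clin_path.exists():
        raise FileNotFoundError(f"missing clinical.csv in {directory}")
    clinical = pd.read_csv(clin_path)
    series = []
    for path in sorted(directory.glob("*_timeseries.tsv")):
        series.append(read_timeseries_tsv(path))
    if not series:
        raise FileNotFoundError(f"no *_timeseries.tsv files in {directory}")
    return series, clinical
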