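"""Global and nodal topology metrics on binary graphs.

Implements the Watts-Strogatz small-world measures (clustering
coefficient Cp, characteristic path length Lp, and their random-network
normalizations gamma, lambda, sigma = gamma/lambda), the Latora-
Marchiori efficiency family (global efficiency Eglob, nodal efficiency
NEg, local efficiency Eloc/NEloc), degree centrality and Brandes
betweenness centrality, plus the sparsity-band AUC summary that makes
the metrics threshold-independent.

Conventions: nodes of degree < 2 contribute clustering and local
efficiency 0 and are included in the means; Lp averages over pairs with
finite distance and sets a flag when the graph is disconnected;
betweenness is reported as raw pair counts (unnormalized).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels
from .connectivity import BinaryGraph, FCMatrix, ThresholdGrid, \
    binarize_at_sparsity

__all__ = [
    "NullEnsemble",
    "MetricProfile",
    "degrees",
    "clustering_coefficients",
    "shortest_path_lengths",
    "characteristic_path_length",
    "global_efficiency",
    "nodal_efficiency",
    "local_efficiency",
    "betweenness",
    "generate_null_ensemble",
    "small_world_metrics",
    "auc_over_grid",
    "profile_subject",
]

GLOBAL_METRICS = ("Cp", "Lp", "gamma", "lambda", "sigma", "Eglob", "Eloc")
NODAL_METRICS = ("DC", "BC", "NEg", "NEloc")


def degrees(g: BinaryGraph) -> np.ndarray:
    return g.degrees()


def clustering_coefficients(g: BinaryGraph) -> tuple[np.ndarray, float]:
    """Per-node clustering C_i = 2 t_i / (k_i (k_i - 1)) and the mean Cp.

    t_i counts edges among the neighbors of i; C_i = 0 for degree < 2.
    """
    a = g.adjacency.astype(np.float64)
    k = a.sum(axis=1)
    # t_i = number of closed neighbor pairs = (A^3)_ii / 2
    tri = np.einsum("ij,jk,ki->i", a, a, a) / 2.0
    denom = k * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, 2.0 * tri / denom, 0.0)
    return c, float(c.mean())


def shortest_path_lengths(g: BinaryGraph) -> np.ndarray:
    """All-pairs unweighted distances (BFS); unreachable pairs are inf."""
    return _kernels.pairwise_distances(g.adjacency)


def characteristic_path_length(
        g: BinaryGraph,
        dist: np.ndarray | None = None) -> tuple[float, bool]:
    """Mean shortest-path length over reachable node pairs.

    Returns (Lp, disconnected_flag); the flag is set when any pair is
    unreachable.  Raises when no finite off-diagonal distance exists.
    """
    if dist is None:
        dist = shortest_path_lengths(g)
    n = dist.shape[0]
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(dist) & off
    if not finite.any():
        raise ValueError("graph has no edges: Lp undefined")
    lp = float(dist[finite].mean())
    disconnected = bool((~np.isfinite(dist) & off).any())
    return lp, disconnected


def _efficiency_from_dist(dist: np.ndarray) -> tuple[float, np.ndarray]:
    n = dist.shape[0]
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    nodal = inv.sum(axis=1) / (n - 1)
    return float(inv.sum() / (n * (n - 1))), nodal


def global_efficiency(g: BinaryGraph,
                      dist: np.ndarray | None = None) -> float:
    """Eglob = mean of 1/d_ij over ordered pairs (1/inf = 0)."""
    if dist is None:
        dist = shortest_path_lengths(g)
    return _efficiency_from_dist(dist)[0]


def nodal_efficiency(g: BinaryGraph,
                     dist: np.ndarray | None = None) -> np.ndarray:
    """NEg(i) = mean of 1/d_ij over j != i."""
    if dist is None:
        dist = shortest_path_lengths(g)
    return _efficiency_from_dist(dist)[1]


def local_efficiency(g: BinaryGraph) -> tuple[float, np.ndarray]:
    """NEloc(i) = global efficiency of i's neighbor-induced subgraph
    (0 for degree < 2); Eloc = mean over all nodes."""
    nodal = _kernels.local_efficiency_nodal(g.adjacency)
    return float(nodal.mean()), nodal


def betweenness(g: BinaryGraph) -> np.ndarray:
    """Brandes betweenness, raw unordered-pair counts per node."""
    return _kernels.betweenness_nodal(g.adjacency)


@dataclass(frozen=True)
class NullEnsemble:
    """Degree-matched rewired random graphs for one source graph."""

    graphs: tuple[BinaryGraph, ...]
    n_swap_attempts: int
    seed: int

    @property
    def n_nulls(self) -> int:
        return len(self.graphs)


def generate_null_ensemble(g: BinaryGraph, n_nulls: int = 100,
                           n_swap_attempts: int | None = None,
                           seed: int = 0) -> NullEnsemble:
    """Maslov-Sneppen degree-preserving rewiring ensemble.

    Each null starts from the source graph and undergoes
    ``n_swap_attempts`` (default 100 * n_edges) double-edge swap
    attempts; an attempt picks two disjoint edges (a,b), (c,d) and
    rewires them to (a,d), (c,b) when neither replacement edge exists.
    The degree sequence is invariant by construction.  Reproducible for
    a fixed seed.
    """
    edges0 = g.edge_list()
    e = edges0.shape[0]
    if e < 2:
        raise ValueError("graph needs at least 2 edges to rewire")
    deg = g.degrees()
    # an edge set with no two disjoint edges is a star or a triangle
    is_star = np.max(deg) == e
    is_triangle = e == 3 and len(np.unique(edges0)) == 3
    if is_star or is_triangle:
        raise ValueError("graph has no two independent edges to swap")
    if n_swap_attempts is None:
        n_swap_attempts = 100 * e
    rng = np.random.default_rng(seed)
    graphs = []
    for _ in range(n_nulls):
        adj = np.ascontiguousarray(g.adjacency.copy())
        edges = np.ascontiguousarray(edges0.copy().astype(np.int64))
        pick = rng.integers(0, e, size=(n_swap_attempts, 2))
        orient = rng.integers(0, 2, size=n_swap_attempts).astype(np.uint8)
        _kernels.double_edge_swap(adj, edges, pick, orient)
        graphs.append(BinaryGraph(adjacency=adj, sparsity=g.sparsity))
    return NullEnsemble(graphs=tuple(graphs),
                        n_swap_attempts=int(n_swap_attempts), seed=seed)


def small_world_metrics(g: BinaryGraph,
                        ens: NullEnsemble) -> tuple[float, float, float]:
    """gamma = Cp/Cp_rand, lambda = Lp/Lp_rand, sigma = gamma/lambda,
    with the random references taken as ensemble means."""
    _, cp = clustering_coefficients(g)
    lp, _ = characteristic_path_length(g)
    cps = []
    lps = []
    for null in ens.graphs:
        _, c = clustering_coefficients(null)
        cps.append(c)
        lps.append(characteristic_path_length(null)[0])
    cp_rand = float(np.mean(cps))
    lp_rand = float(np.mean(lps))
    if cp_rand == 0 or lp_rand == 0:
        raise ValueError("null ensemble has zero mean Cp or Lp; "
                         "normalization undefined")
    gamma = cp / cp_rand
    lam = lp / lp_rand
    return gamma, lam, gamma / lam


def auc_over_grid(values, grid: ThresholdGrid) -> float:
    """Trapezoidal area under a metric curve across the sparsity grid."""
    values = np.asarray(values, dtype=float)
    s = np.asarray(grid.sparsities)
    if len(s) < 2:
        raise ValueError("AUC needs at least 2 grid points")
    if values.shape[0] != len(s):
        raise ValueError("values and grid must have equal length")
    return float(np.trapezoid(values, s))


@dataclass(frozen=True)
class MetricProfile:
    """All metrics for one subject across the threshold grid.

    ``global_metrics`` is indexed by sparsity with columns Cp, Lp, gamma,
    lambda, sigma, Eglob, Eloc (gamma/lambda/sigma are NaN when the null
    ensemble was skipped); ``nodal_metrics`` is long-format
    (node_id, sparsity, DC, BC, NEg, NEloc).  ``auc_global`` /
    ``auc_nodal`` hold the trapezoidal summaries.
    """

    subject_id: str
    grid: ThresholdGrid
    global_metrics: pd.DataFrame
    nodal_metrics: pd.DataFrame
    auc_global: pd.Series
    auc_nodal: pd.DataFrame
    disconnected_at: tuple[float, ...] = field(default_factory=tuple)


def profile_subject(fc: FCMatrix, grid: ThresholdGrid | None = None,
                    n_nulls: int = 0,
                    n_swap_attempts: int | None = None,
                    seed: int = 0) -> MetricProfile:
    """Binarize across the grid and compute every metric plus its AUC.

    With ``n_nulls`` = 0 the ensemble normalization (gamma, lambda,
    sigma) is skipped and those columns are NaN.  Deterministic for a
    fixed seed: the null ensemble at grid point k is seeded from
    (seed, k) through a NumPy SeedSequence.
    """
    if grid is None:
        grid = ThresholdGrid()
    glob_rows = []
    nodal_rows = []
    disconnected = []
    for k, s in enumerate(grid):
        g = binarize_at_sparsity(fc, s)
        dist = shortest_path_lengths(g)
        c_nodal, cp = clustering_coefficients(g)
        lp, disc = characteristic_path_length(g, dist)
        if disc:
            disconnected.append(s)
        eglob, neg = _efficiency_from_dist(dist)
        eloc, neloc = local_efficiency(g)
        if n_nulls > 0:
            ens_seed = int(
                np.random.SeedSequence([seed, k]).generate_state(1)[0]
                % (2 ** 31))
            ens = generate_null_ensemble(g, n_nulls, n_swap_attempts,
                                         seed=ens_seed)
            gamma, lam, sigma = small_world_metrics(g, ens)
        else:
            gamma = lam = sigma = np.nan
        glob_rows.append({"sparsity": s, "Cp": cp, "Lp": lp,
                          "gamma": gamma, "lambda": lam, "sigma": sigma,
                          "Eglob": eglob, "Eloc": eloc})
        dc = g.degrees()
        bc = betweenness(g)
        for i in range(g.n_nodes):
            nodal_rows.append({"node_id": i, "sparsity": s,
                               "DC": float(dc[i]), "BC": float(bc[i]),
                               "NEg": float(neg[i]),
                               "NEloc": float(neloc[i])})
    global_df = pd.DataFrame(glob_rows).set_index("sparsity")
    nodal_df = pd.DataFrame(nodal_rows)

    auc_global = pd.Series(
        {m: auc_over_grid(global_df[m].to_numpy(), grid)
         for m in GLOBAL_METRICS
         if not global_df[m].isna().any()},
        dtype=float)
    wide = {m: nodal_df.pivot(index="node_id", columns="sparsity",
                              values=m) for m in NODAL_METRICS}
    auc_nodal = pd.DataFrame(
        {m: [auc_over_grid(wide[m].loc[i].to_numpy(), grid)
             for i in wide[m].index] for m in NODAL_METRICS})
    auc_nodal.index.name = "node_id"
    return MetricProfile(
        subject_id=fc.subject_id, grid=grid, global_metrics=global_df,
        nodal_metrics=nodal_df, auc_global=auc_global, auc_nodal=auc_nodal,
        disconnected_at=tuple(disconnected))
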