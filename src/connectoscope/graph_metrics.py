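"""Global and nodal graph topology over the sparsity grid.

Eight global metrics (modularity Q, global/local efficiency, clustering
Cp, normalized clustering gamma, normalized path length lambda,
small-worldness sigma = gamma/lambda, characteristic path length Lp) and
six nodal metrics (betweenness, degree, nodal clustering, nodal
efficiency, nodal local efficiency, nodal shortest path) are computed per
binary graph, and each metric curve across the 46 sparsity thresholds is
summarized by its trapezoidal AUC.

Conventions for disconnected graphs (routine at low sparsity): Lp and
nodal shortest path average over *reachable* pairs only; efficiencies use
1/inf = 0. Nodes with degree < 2 contribute 0 clustering and 0 local
efficiency. gamma and lambda normalize against degree-preserving
(double-edge-swap) null networks; betweenness is unnormalized pair
counts with fractional credit over tied shortest paths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import igraph as ig
import numpy as np
import pandas as pd
from numba import njit
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

from .connectome import BinaryGraph

GLOBAL_METRIC_NAMES = ["Q", "Eglobal", "Elocal", "Cp", "gamma", "lambda",
                       "sigma", "Lp"]
NODAL_METRIC_NAMES = ["betweenness", "degree", "nodal_cp", "nodal_efficiency",
                      "nodal_local_efficiency", "nodal_shortest_path"]


@dataclass
class GlobalMetricValues:
    Q: float
    Eglobal: float
    Elocal: float
    Cp: float
    Lp: float
    degenerate: bool = False


@dataclass
class MetricCurves:
    """All metrics per sparsity plus their AUC summaries."""

    sparsities: np.ndarray                  # (S,)
    global_curves: pd.DataFrame             # S x 8
    nodal_curves: dict[str, np.ndarray]     # metric -> (S, n_nodes)
    global_auc: pd.Series                   # 8
    nodal_auc: pd.DataFrame                 # n_nodes x 6


def _adjacency_lists(adj: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """CSR-style neighbor lists (offsets, neighbors) of a boolean adjacency."""
    rows, cols = np.nonzero(adj)
    off = np.zeros(adj.shape[0] + 1, np.int64)
    np.cumsum(np.bincount(rows, minlength=adj.shape[0]), out=off[1:])
    return off, cols.astype(np.int64)


@njit(cache=False)
def _all_pairs_bfs(n, off, nbr):  # pragma: no cover - numba kernel
    dist = np.full((n, n), -1, np.int64)
    queue = np.empty(n, np.int64)
    for s in range(n):
        dist[s, s] = 0
        queue[0] = s
        head, tail = 0, 1
        while head < tail:
            u = queue[head]
            head += 1
            du = dist[s, u]
            for k in range(off[u], off[u + 1]):
                v = nbr[k]
                if dist[s, v] < 0:
                    dist[s, v] = du + 1
                    queue[tail] = v
                    tail += 1
    return dist


def shortest_paths(graph: BinaryGraph) -> np.ndarray:
    """Unweighted BFS distance matrix; unreachable pairs are inf."""
    off, nbr = _adjacency_lists(graph.adjacency)
    d = _all_pairs_bfs(graph.n_nodes, off, nbr).astype(float)
    d[d < 0] = np.inf
    return d


def _efficiency_from_dist(dist: np.ndarray) -> tuple[float, np.ndarray]:
    """(global efficiency, per-node efficiency) from a distance matrix."""
    n = dist.shape[0]
    if n < 2:
        return 0.0, np.zeros(n)
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist
    np.fill_diagonal(inv, 0.0)
    inv[~np.isfinite(inv)] = 0.0
    nodal = inv.sum(axis=1) / (n - 1)
    return float(nodal.mean()), nodal


def _char_path_from_dist(dist: np.ndarray) -> tuple[float, np.ndarray]:
    """(Lp over reachable pairs, per-node mean finite distance)."""
    n = dist.shape[0]
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(dist) & off
    counts = finite.sum(axis=1)
    sums = np.where(finite, dist, 0.0).sum(axis=1)
    nodal = np.divide(sums, counts, out=np.zeros(n), where=counts > 0)
    total = finite.sum()
    lp = float(np.where(finite, dist, 0.0).sum() / total) if total else 0.0
    return lp, nodal


def _clustering(adj: np.ndarray) -> np.ndarray:
    A = adj.astype(np.float64)
    deg = A.sum(axis=1)
    tri = ((A @ A) * A).sum(axis=1) / 2.0
    denom = deg * (deg - 1) / 2.0
    return np.divide(tri, denom, out=np.zeros_like(tri), where=denom > 0)


@njit(cache=False)
def _local_efficiency_kernel(n, off, nbr):  # pragma: no cover - numba kernel
    out = np.zeros(n)
    local = np.full(n, -1, np.int64)      # global -> subgraph index
    sub_off = np.empty(n + 1, np.int64)
    sub_nbr = np.empty(nbr.shape[0], np.int64)
    dist = np.empty(n, np.int64)
    queue = np.empty(n, np.int64)
    for i in range(n):
        cnt = off[i + 1] - off[i]
        if cnt < 2:
            continue
        for a in range(cnt):
            local[nbr[off[i] + a]] = a
        # neighbor lists of the neighbor-induced subgraph
        sub_off[0] = 0
        p = 0
        for a in range(cnt):
            g = nbr[off[i] + a]
            for k in range(off[g], off[g + 1]):
                la = local[nbr[k]]
                if la >= 0:
                    sub_nbr[p] = la
                    p += 1
            sub_off[a + 1] = p
        # all-sources BFS on the subgraph
        total = 0.0
        for s in range(cnt):
            for v in range(cnt):
                dist[v] = -1
            dist[s] = 0
            queue[0] = s
            head, tail = 0, 1
            while head < tail:
                u = queue[head]
                head += 1
                du = dist[u]
                for k in range(sub_off[u], sub_off[u + 1]):
                    v = sub_nbr[k]
                    if dist[v] < 0:
                        dist[v] = du + 1
                        queue[tail] = v
                        tail += 1
            for t in range(cnt):
                if t != s and dist[t] > 0:
                    total += 1.0 / dist[t]
        out[i] = total / (cnt * (cnt - 1))
        for a in range(cnt):
            local[nbr[off[i] + a]] = -1
    return out


def _local_efficiency(adj: np.ndarray, deg: np.ndarray | None = None) -> np.ndarray:
    """Per-node global efficiency of the neighbor-induced subgraph."""
    off, nbr = _adjacency_lists(adj)
    return _local_efficiency_kernel(adj.shape[0], off, nbr)


def _to_igraph(adj: np.ndarray) -> ig.Graph:
    iu, ju = np.nonzero(np.triu(adj, k=1))
    return ig.Graph(n=adj.shape[0], edges=list(zip(iu.tolist(), ju.tolist())))


def modularity_q(graph: BinaryGraph) -> float:
    """Newman modularity of the best greedy-agglomeration (CNM) partition."""
    if graph.edge_count == 0:
        return 0.0
    g = _to_igraph(graph.adjacency)
    clustering = g.community_fastgreedy().as_clustering()
    return float(g.modularity(clustering.membership))


def global_metrics(graph: BinaryGraph, dist: np.ndarray | None = None,
                   local_eff: np.ndarray | None = None) -> GlobalMetricValues:
    """Q, global/local efficiency, clustering, characteristic path length."""
    if graph.edge_count == 0:
        return GlobalMetricValues(0.0, 0.0, 0.0, 0.0, 0.0, degenerate=True)
    if dist is None:
        dist = shortest_paths(graph)
    eglob, _ = _efficiency_from_dist(dist)
    lp, _ = _char_path_from_dist(dist)
    cp = float(_clustering(graph.adjacency).mean())
    if local_eff is None:
        local_eff = _local_efficiency(graph.adjacency, None)
    return GlobalMetricValues(modularity_q(graph), eglob,
                              float(local_eff.mean()), cp, lp)


def nodal_metrics(graph: BinaryGraph, dist: np.ndarray | None = None,
                  local_eff: np.ndarray | None = None) -> pd.DataFrame:
    """Per-node metric table (n_nodes x 6, columns NODAL_METRIC_NAMES)."""
    adj = graph.adjacency
    n = graph.n_nodes
    if dist is None:
        dist = shortest_paths(graph)
    deg = adj.sum(axis=1).astype(float)
    _, nodal_eff = _efficiency_from_dist(dist)
    _, nodal_path = _char_path_from_dist(dist)
    if graph.edge_count:
        btw = np.asarray(_to_igraph(adj).betweenness(), float)
    else:
        btw = np.zeros(n)
    if local_eff is None:
        local_eff = _local_efficiency(adj, deg)
    return pd.DataFrame({
        "betweenness": btw,
        "degree": deg,
        "nodal_cp": _clustering(adj),
        "nodal_efficiency": nodal_eff,
        "nodal_local_efficiency": local_eff,
        "nodal_shortest_path": nodal_path,
    })


@njit(cache=False)
def _swap_kernel(A, edges, pick1, pick2, flip, n_swaps):  # pragma: no cover
    successes = 0
    for k in range(pick1.shape[0]):
        if successes >= n_swaps:
            break
        i1, i2 = pick1[k], pick2[k]
        if i1 == i2:
            continue
        a, b = edges[i1, 0], edges[i1, 1]
        c, d = edges[i2, 0], edges[i2, 1]
        if flip[k]:
            c, d = d, c
        if a == d or c == b:
            continue
        if A[a, d] or A[c, b]:
            continue
        A[a, b] = False
        A[b, a] = False
        A[c, d] = False
        A[d, c] = False
        A[a, d] = True
        A[d, a] = True
        A[c, b] = True
        A[b, c] = True
        edges[i1, 1] = d
        edges[i2, 0] = c
        edges[i2, 1] = b
        successes += 1
    return successes


def rewire_null(graph: BinaryGraph, n_swaps: int | None = None,
                seed: int | np.random.Generator = 0) -> BinaryGraph:
    """Degree-preserving Maslov-Sneppen double-edge-swap null network.

    Defaults to 10x the edge count of attempted swaps. Self-loops and
    multi-edges are never introduced. If no valid swap is found within the
    bounded attempt budget (2x the requested swaps plus 100), the input
    graph is returned unchanged with a warning.
    """
    E = graph.edge_count
    if n_swaps is None:
        n_swaps = 10 * E
    A = graph.adjacency.copy()
    if E < 2 or n_swaps == 0:
        if E < 2:
            warnings.warn("graph has < 2 edges; returning input unchanged")
        return BinaryGraph(A, graph.sparsity, E)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    iu, ju = np.nonzero(np.triu(A, k=1))
    edges = np.column_stack([iu, ju]).astype(np.int64)
    attempts = 2 * n_swaps + 100
    pick = rng.integers(0, E, size=(2, attempts))
    flip = rng.integers(0, 2, size=attempts).astype(np.uint8)
    ok = _swap_kernel(A, edges, pick[0], pick[1], flip, n_swaps)
    if ok == 0:
        warnings.warn("no valid double-edge swap found; returning input unchanged")
        return BinaryGraph(graph.adjacency.copy(), graph.sparsity, E)
    return BinaryGraph(A, graph.sparsity, E)


def normalized_small_world(graph: BinaryGraph, n_rand: int = 100,
                           n_swaps: int | None = None,
                           seed: int | np.random.Generator = 0,
                           dist: np.ndarray | None = None
                           ) -> tuple[float, float, float]:
    """(gamma, lambda, sigma) against degree-preserving null networks.

    gamma = Cp / <Cp_null>, lambda = Lp / <Lp_null>, sigma = gamma/lambda.
    """
    if graph.edge_count == 0:
        raise ValueError("cannot normalize an empty graph")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if dist is None:
        dist = shortest_paths(graph)
    cp = float(_clustering(graph.adjacency).mean())
    lp, _ = _char_path_from_dist(dist)
    null_cp = np.empty(n_rand)
    null_lp = np.empty(n_rand)
    for k in range(n_rand):
        null = rewire_null(graph, n_swaps=n_swaps, seed=rng)
        nd = shortest_paths(null)
        null_cp[k] = _clustering(null.adjacency).mean()
        null_lp[k], _ = _char_path_from_dist(nd)
    mean_cp, mean_lp = null_cp.mean(), null_lp.mean()
    if mean_cp == 0 or mean_lp == 0:
        raise ValueError("degenerate null model (zero mean Cp or Lp)")
    gamma = cp / mean_cp
    lam = lp / mean_lp
    return gamma, lam, gamma / lam


def metric_auc(curve: np.ndarray, grid: np.ndarray) -> float:
    """Trapezoidal integral of a metric curve over the sparsity grid."""
    curve = np.asarray(curve, float)
    grid = np.asarray(grid, float)
    if curve.shape[0] != grid.shape[0] or curve.shape[0] < 2:
        raise ValueError("curve and grid must have equal length >= 2")
    return float(np.trapezoid(curve, grid, axis=0))


def connectome_curves(graphs: list[BinaryGraph], n_rand: int = 100,
                      seed: int | np.random.Generator = 0,
                      n_swaps: int | None = None) -> MetricCurves:
    """All global and nodal metrics plus AUCs for one subject's graph series."""
    if len(graphs) < 2:
        raise ValueError("need a graph series of length >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    S = len(graphs)
    n = graphs[0].n_nodes
    grid = np.array([g.sparsity for g in graphs])
    glob = np.empty((S, len(GLOBAL_METRIC_NAMES)))
    nodal = {m: np.empty((S, n)) for m in NODAL_METRIC_NAMES}
    for k, g in enumerate(graphs):
        dist = shortest_paths(g)
        local_eff = _local_efficiency(g.adjacency, None)
        gm = global_metrics(g, dist=dist, local_eff=local_eff)
        gamma, lam, sigma = normalized_small_world(
            g, n_rand=n_rand, n_swaps=n_swaps, seed=rng, dist=dist)
        glob[k] = [gm.Q, gm.Eglobal, gm.Elocal, gm.Cp, gamma, lam, sigma, gm.Lp]
        nm = nodal_metrics(g, dist=dist, local_eff=local_eff)
        for m in NODAL_METRIC_NAMES:
            nodal[m][k] = nm[m].to_numpy()
    global_curves = pd.DataFrame(glob, index=grid, columns=GLOBAL_METRIC_NAMES)
    global_auc = pd.Series(
        {m: metric_auc(glob[:, i], grid)
         for i, m in enumerate(GLOBAL_METRIC_NAMES)})[GLOBAL_METRIC_NAMES]
    nodal_auc = pd.DataFrame(
        {m: np.trapezoid(nodal[m], grid, axis=0) for m in NODAL_METRIC_NAMES})
    return MetricCurves(grid, global_curves, nodal, global_auc, nodal_auc)
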