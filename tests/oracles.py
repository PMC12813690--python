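"""Independent brute-force oracles used to cross-check the package.

Everything here is deliberately naive (Floyd-Warshall, explicit DFT sums,
textbook formulas) and shares no code with the implementation under test.
"""

from __future__ import annotations

import cmath
import itertools

import numpy as np

INF = float("inf")


# ---------------------------------------------------------------- graphs

def fw_distances(adj) -> list[list[float]]:
    """Floyd-Warshall all-pairs distances on a boolean adjacency matrix."""
    n = len(adj)
    d = [[0 if i == j else (1 if adj[i][j] else INF) for j in range(n)]
         for i in range(n)]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i][k] + d[k][j] < d[i][j]:
                    d[i][j] = d[i][k] + d[k][j]
    return d


def path_counts(adj, dist) -> list[list[int]]:
    """Number of shortest paths between each ordered pair (DP by distance)."""
    n = len(adj)
    sigma = [[0] * n for _ in range(n)]
    for s in range(n):
        sigma[s][s] = 1
        order = sorted((dist[s][t], t) for t in range(n) if dist[s][t] < INF)
        for _, t in order:
            if t == s:
                continue
            sigma[s][t] = sum(sigma[s][u] for u in range(n)
                              if adj[u][t] and dist[s][u] == dist[s][t] - 1)
    return sigma


def bf_betweenness(adj) -> list[float]:
    """Unnormalized betweenness with fractional credit over tied paths."""
    n = len(adj)
    dist = fw_distances(adj)
    sigma = path_counts(adj, dist)
    out = [0.0] * n
    for v in range(n):
        for s in range(n):
            for t in range(s + 1, n):
                if v in (s, t) or dist[s][t] == INF or sigma[s][t] == 0:
                    continue
                if dist[s][v] + dist[v][t] == dist[s][t]:
                    out[v] += sigma[s][v] * sigma[v][t] / sigma[s][t]
    return out


def bf_degree(adj) -> list[int]:
    return [sum(row) for row in adj]


def bf_nodal_clustering(adj) -> list[float]:
    n = len(adj)
    out = []
    for i in range(n):
        nb = [j for j in range(n) if adj[i][j]]
        k = len(nb)
        if k < 2:
            out.append(0.0)
            continue
        links = sum(1 for a, b in itertools.combinations(nb, 2) if adj[a][b])
        out.append(links / (k * (k - 1) / 2))
    return out


def bf_global_efficiency(adj) -> float:
    n = len(adj)
    if n < 2:
        return 0.0
    dist = fw_distances(adj)
    return sum(1.0 / dist[i][j] for i in range(n) for j in range(n)
               if i != j and dist[i][j] < INF) / (n * (n - 1))


def bf_nodal_efficiency(adj) -> list[float]:
    n = len(adj)
    dist = fw_distances(adj)
    return [sum(1.0 / dist[i][j] for j in range(n)
                if j != i and dist[i][j] < INF) / (n - 1) for i in range(n)]


def bf_local_efficiency(adj) -> list[float]:
    n = len(adj)
    out = []
    for i in range(n):
        nb = [j for j in range(n) if adj[i][j]]
        if len(nb) < 2:
            out.append(0.0)
            continue
        sub = [[adj[a][b] for b in nb] for a in nb]
        out.append(bf_global_efficiency(sub))
    return out


def bf_char_path(adj) -> float:
    n = len(adj)
    dist = fw_distances(adj)
    finite = [dist[i][j] for i in range(n) for j in range(n)
              if i != j and dist[i][j] < INF]
    return sum(finite) / len(finite) if finite else 0.0


def bf_nodal_path(adj) -> list[float]:
    n = len(adj)
    dist = fw_distances(adj)
    out = []
    for i in range(n):
        finite = [dist[i][j] for j in range(n) if j != i and dist[i][j] < INF]
        out.append(sum(finite) / len(finite) if finite else 0.0)
    return out


def bf_modularity(adj, communities) -> float:
    """Newman modularity of a given partition (list of vertex sets)."""
    n = len(adj)
    m2 = sum(sum(row) for row in adj)  # 2m
    q = 0.0
    for c in communities:
        e_in = sum(adj[i][j] for i in c for j in c)  # counts both directions
        deg = sum(sum(adj[i]) for i in c)
        q += e_in / m2 - (deg / m2) ** 2
    return q


# ---------------------------------------------------------------- spectra

def dft_sqrt_power(series, tr) -> tuple[list[float], list[float]]:
    """Explicit-sum one-sided sqrt periodogram and its frequencies."""
    x = list(map(float, series))
    T = len(x)
    n_bins = T // 2 + 1
    amps, freqs = [], []
    for k in range(n_bins):
        s = sum(x[t] * cmath.exp(-2j * cmath.pi * k * t / T) for t in range(T))
        amps.append(abs(s) / T ** 0.5)
        freqs.append(k / (T * tr))
    return amps, freqs


def dft_alff(series, tr, band) -> float:
    amps, freqs = dft_sqrt_power(series, tr)
    sel = [a for a, f in zip(amps[1:], freqs[1:]) if band[0] <= f <= band[1]]
    return sum(sel) / len(sel)


def dft_falff(series, tr, band) -> float:
    amps, freqs = dft_sqrt_power(series, tr)
    sel = sum(a for a, f in zip(amps[1:], freqs[1:]) if band[0] <= f <= band[1])
    return sel / sum(amps[1:])


# ----------------------------------------------------------- rank statistics

def rank_with_midranks(x) -> list[float]:
    order = sorted(range(len(x)), key=lambda i: x[i])
    ranks = [0.0] * len(x)
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        mid = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = mid
        i = j + 1
    return ranks


def kendall_w_oracle(series_set) -> float:
    """Direct rank-sum Kendall concordance."""
    m = len(series_set)
    n = len(series_set[0])
    ranks = [rank_with_midranks(s) for s in series_set]
    R = [sum(ranks[i][t] for i in range(m)) for t in range(n)]
    Rbar = sum(R) / n
    ss = sum((r - Rbar) ** 2 for r in R)
    return 12.0 * ss / (m ** 2 * (n ** 3 - n))


# ------------------------------------------------------------- statistics

def bh_stepup(pvals, q) -> list[bool]:
    """Textbook Benjamini-Hochberg step-up rejections."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    k_max = 0
    for rank, idx in enumerate(order, start=1):
        if pvals[idx] <= rank * q / m:
            k_max = rank
    reject = [False] * m
    for rank, idx in enumerate(order, start=1):
        if rank <= k_max:
            reject[idx] = True
    return reject


def bh_adjusted(pvals) -> list[float]:
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        val = min(prev, pvals[idx] * m / rank)
        adj[idx] = val
        prev = val
    return adj


def ols_group_t(y, group, covariates=None):
    """Normal-equations OLS t on the group column (with intercept)."""
    y = np.asarray(y, float)
    n = len(y)
    cols = [np.ones(n), np.asarray(group, float)]
    if covariates is not None:
        Z = np.asarray(covariates, float)
        if Z.ndim == 1:
            Z = Z[:, None]
        cols.extend(Z.T)
    X = np.column_stack(cols)
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    df = n - X.shape[1]
    s2 = resid @ resid / df
    se = np.sqrt(s2 * np.linalg.inv(XtX)[1, 1])
    t = beta[1] / se
    from scipy import stats
    return t, 2 * stats.t.sf(abs(t), df), df
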