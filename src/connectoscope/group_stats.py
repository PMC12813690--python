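"""Group comparisons: covariate-adjusted voxelwise GLM t-maps with
permutation-based cluster correction, and FDR-controlled network-metric
tests.

The voxelwise model is value ~ intercept + group + covariates, with the
two-sided t on the group coefficient (df = n - K - 2 for K covariates).
Cluster correction permutes group labels, records the maximum
suprathreshold (|t|, two-tailed) cluster size per permutation under
6-connectivity, and keeps observed clusters larger than the
(1 - cluster_p) quantile of that null. Network-metric AUCs are compared
by two-sample t-tests with Benjamini-Hochberg control within each metric
family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from .graph_metrics import GLOBAL_METRIC_NAMES, NODAL_METRIC_NAMES, MetricCurves
from .voxel_metrics import VoxelMap


@dataclass
class StatMap:
    t_values: np.ndarray
    p_values: np.ndarray
    df: int
    mask: np.ndarray
    cluster_labels: np.ndarray | None = None
    surviving_clusters: list[dict] = field(default_factory=list)


def _design(group: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    n = len(group)
    cols = [np.ones(n), np.asarray(group, float)]
    if covariates is not None:
        Z = np.asarray(covariates, float)
        if Z.ndim == 1:
            Z = Z[:, None]
        cols.extend(Z.T)
    return np.column_stack(cols)


def _glm_t_vec(Y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """t and two-sided p on the group column (column 1) of X, per column of Y."""
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need n > {p} subjects for this design")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("rank-deficient design (collinear covariates)")
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ (X.T @ Y)
    resid = Y - X @ beta
    df = n - p
    sigma2 = (resid ** 2).sum(axis=0) / df
    se = np.sqrt(sigma2 * XtX_inv[1, 1])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta[1] / se, 0.0)
    pvals = 2.0 * stats.t.sf(np.abs(t), df)
    return t, pvals, df


def glm_group_t(values: np.ndarray, group: np.ndarray,
                covariates: np.ndarray | None = None) -> tuple[float, float, int]:
    """Covariate-adjusted two-sample comparison via OLS.

    Returns (t, two-sided p, df) for the group coefficient. With no
    covariates this equals the pooled two-sample t statistic.
    """
    X = _design(np.asarray(group), covariates)
    t, p, df = _glm_t_vec(np.asarray(values, float)[:, None], X)
    return float(t[0]), float(p[0]), df


def voxelwise_group_map(maps: list[VoxelMap], group: np.ndarray,
                        covariates: np.ndarray | None = None) -> StatMap:
    """Per-voxel covariate-adjusted group t-map over a shared mask."""
    mask = maps[0].mask
    for m in maps[1:]:
        if m.mask.shape != mask.shape or not (m.mask == mask).all():
            raise ValueError("subject maps do not share a common mask")
    Y = np.stack([m.values[mask] for m in maps])  # n x V
    X = _design(np.asarray(group), covariates)
    t, p, df = _glm_t_vec(Y, X)
    tmap = np.zeros(mask.shape)
    pmap = np.ones(mask.shape)
    tmap[mask] = t
    pmap[mask] = p
    return StatMap(tmap, pmap, df, mask.copy())


_CLUSTER_STRUCT = ndimage.generate_binary_structure(3, 1)  # faces only


def _cluster_sizes(supra: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels, n = ndimage.label(supra, structure=_CLUSTER_STRUCT)
    if n == 0:
        return labels, np.array([], int)
    return labels, np.bincount(labels.ravel())[1:]


def _residualize(M: np.ndarray, X: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(X, M, rcond=None)
    return M - X @ beta


def permutation_cluster_correct(maps: list[VoxelMap], group: np.ndarray,
                                covariates: np.ndarray | None = None,
                                n_perm: int = 1000, voxel_p: float = 0.01,
                                cluster_p: float = 0.01,
                                seed: int | np.random.Generator = 0) -> StatMap:
    """Two-tailed permutation cluster-size correction of the group t-map.

    Covariates stay attached to their subjects while group labels are
    permuted; per permutation the adjusted t-map is recomputed through the
    Frisch-Waugh residualization identity, which is algebraically exact
    for OLS and keeps the loop to one matrix product per permutation.
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    if 1.0 / (n_perm + 1) > cluster_p:
        warnings.warn(f"{n_perm} permutations cannot resolve "
                      f"cluster_p={cluster_p}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    stat = voxelwise_group_map(maps, group, covariates)
    mask = stat.mask
    n = len(maps)
    g = np.asarray(group, float)
    K = 0 if covariates is None else np.atleast_2d(np.asarray(covariates).T).shape[0]
    df = n - K - 2
    tcrit = stats.t.ppf(1.0 - voxel_p / 2.0, df)

    # residualize data and labels against intercept + covariates once
    Z = _design(np.zeros(n), covariates)[:, [0] + list(range(2, 2 + K))]
    Y = np.stack([m.values[mask] for m in maps])      # n x V
    Yr = _residualize(Y, Z)
    ss_y = (Yr ** 2).sum(axis=0)

    def t_of(perm_g: np.ndarray) -> np.ndarray:
        gr = _residualize(perm_g[:, None], Z)[:, 0]
        gg = (gr ** 2).sum()
        if gg <= 0:
            return np.zeros(Yr.shape[1])
        b = (gr @ Yr) / gg
        rss = ss_y - b ** 2 * gg
        sigma2 = np.maximum(rss, 0.0) / df
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(sigma2 > 0, b * np.sqrt(gg) / np.sqrt(sigma2), 0.0)
        return t

    null_max = np.zeros(n_perm, int)
    supra3 = np.zeros(mask.shape, bool)
    for i in range(n_perm):
        t = t_of(rng.permutation(g))
        supra3[mask] = np.abs(t) > tcrit
        _, sizes = _cluster_sizes(supra3)
        null_max[i] = sizes.max() if sizes.size else 0

    supra3[mask] = np.abs(stat.t_values[mask]) > tcrit
    labels, sizes = _cluster_sizes(supra3)
    threshold = np.quantile(null_max, 1.0 - cluster_p)
    surviving = []
    for ci, size in enumerate(sizes, start=1):
        corrected = (1 + (null_max >= size).sum()) / (n_perm + 1)
        if size > threshold:
            inside = labels == ci
            peak_flat = np.abs(np.where(inside, stat.t_values, 0)).argmax()
            surviving.append({
                "size": int(size),
                "peak_voxel": tuple(int(v) for v in
                                    np.unravel_index(peak_flat, mask.shape)),
                "corrected_p": float(corrected),
            })
    stat.cluster_labels = labels
    stat.surviving_clusters = surviving
    return stat


def bh_fdr(p_values: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (adjusted p, rejection flags)."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p.copy(), np.zeros(0, bool)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject


def metric_group_tests(curves: list[MetricCurves], group: np.ndarray,
                       q: float = 0.05,
                       covariates: np.ndarray | None = None) -> pd.DataFrame:
    """t-tests on every metric AUC, BH-corrected within each metric family.

    Families: the 8 global metrics as one family, and each nodal metric's
    90 nodes as its own family. Covariates default to none (plain
    two-sample t), switchable.
    """
    if len(curves) != len(group):
        raise ValueError("one MetricCurves per subject required")
    group = np.asarray(group)
    if (group == 1).sum() < 2 or (group == 0).sum() < 2:
        raise ValueError("need >= 2 subjects per group")
    rows = []
    g1, g0 = group == 1, group == 0

    def _test_family(values: np.ndarray, names: list[tuple[str, str]]):
        out = []
        for j, (metric, node) in enumerate(names):
            v = values[:, j]
            t, p, _ = glm_group_t(v, group, covariates)
            out.append({
                "metric": metric, "node": node,
                "mean_patients": float(v[g1].mean()),
                "sd_patients": float(v[g1].std(ddof=1)),
                "mean_controls": float(v[g0].mean()),
                "sd_controls": float(v[g0].std(ddof=1)),
                "t": t, "p": p,
            })
        p_adj, rej = bh_fdr(np.array([r["p"] for r in out]), q)
        for r, pa, rj in zip(out, p_adj, rej):
            r["p_fdr"] = float(pa)
            r["significant"] = bool(rj)
        return out

    glob = np.stack([c.global_auc.to_numpy() for c in curves])
    rows += _test_family(glob, [(m, "global") for m in GLOBAL_METRIC_NAMES])
    n_nodes = curves[0].nodal_auc.shape[0]
    for m in NODAL_METRIC_NAMES:
        vals = np.stack([c.nodal_auc[m].to_numpy() for c in curves])
        rows += _test_family(vals, [(m, f"node{j + 1:02d}")
                                    for j in range(n_nodes)])
    return pd.DataFrame(rows)
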