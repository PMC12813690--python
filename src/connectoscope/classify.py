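"""Multi-kernel SVM classification of connectome features under nested LOOCV.

Three feature blocks per subject: C (4005 Fisher-z edge weights, upper
triangle in fixed lexicographic order), G (8 global-metric AUCs), and N
(540 nodal-metric AUCs). Within each outer leave-one-out fold, a
two-sample t-test on the training subjects selects C and N features
(G is always passed whole); an inner LOOCV over the training subjects
picks the SVM cost C and the simplex kernel weights; the held-out subject
never influences selection, standardization, or tuning. Consensus
connections are the C features selected in every outer fold.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.svm import SVC

try:  # scikit-learn's bundled libsvm bindings, used only to score the
    # innermost LOOCV grid without estimator-construction overhead;
    # predictions are identical to SVC(kernel="precomputed").
    from sklearn.svm import _libsvm as _llsvm
    _llsvm.set_verbosity_wrap(0)
except ImportError:  # pragma: no cover
    _llsvm = None

from .graph_metrics import GLOBAL_METRIC_NAMES, NODAL_METRIC_NAMES, MetricCurves

N_NODES = 90
N_EDGES = N_NODES * (N_NODES - 1) // 2  # 4005

DEFAULT_C_GRID = tuple(2.0 ** k for k in range(-5, 6))
DEFAULT_BETA_STEP = 0.1


def edge_index_to_pair(index: int, n_nodes: int = N_NODES) -> tuple[int, int]:
    """C-block index -> 1-based (i, j) node pair, lexicographic order.

    Index 0 is edge (1, 2); the last index is (n-1, n).
    """
    if not 0 <= index < n_nodes * (n_nodes - 1) // 2:
        raise IndexError("edge index out of range")
    i = 0
    remaining = index
    row_len = n_nodes - 1
    while remaining >= row_len:
        remaining -= row_len
        i += 1
        row_len -= 1
    return i + 1, i + 2 + remaining


def pair_to_edge_index(i: int, j: int, n_nodes: int = N_NODES) -> int:
    """1-based node pair -> C-block index (inverse of edge_index_to_pair)."""
    if not (1 <= i < j <= n_nodes):
        raise IndexError("need 1 <= i < j <= n_nodes")
    i0, j0 = i - 1, j - 1
    return i0 * n_nodes - i0 * (i0 + 1) // 2 + (j0 - i0 - 1)


@dataclass
class FeatureBlocks:
    """One subject's classifier features."""

    C: np.ndarray
    G: np.ndarray
    N: np.ndarray
    subject_id: str
    group: int

    def __post_init__(self):
        for name, arr, expected in (("G", self.G, len(GLOBAL_METRIC_NAMES)),):
            if arr.shape != (expected,):
                raise ValueError(f"{name} block must have length {expected}")
        if self.C.ndim != 1 or self.N.ndim != 1:
            raise ValueError("feature blocks must be vectors")
        for arr in (self.C, self.G, self.N):
            if not np.all(np.isfinite(arr)):
                raise ValueError("feature blocks must be finite")

    def block(self, name: str) -> np.ndarray:
        return {"C": self.C, "G": self.G, "N": self.N}[name]


@dataclass
class ClassificationResult:
    folds: pd.DataFrame                 # per held-out subject
    selected_C: list[np.ndarray]        # per fold, C-block indices
    selected_N: list[np.ndarray]
    consensus_C: np.ndarray             # intersection across folds
    summary: dict
    combo: tuple[str, ...] = ("C", "G", "N")


def assemble_features(z_matrix, curves: MetricCurves, subject_id: str = "",
                      group: int = 0) -> FeatureBlocks:
    """Flatten one subject's connectome into fixed-order feature blocks.

    C: upper triangle of the Fisher-z matrix, row-major lexicographic.
    G: global-metric AUCs in GLOBAL_METRIC_NAMES order.
    N: nodal-metric AUCs, metric-major (metric 1 nodes 1..90, metric 2 ...).
    """
    if z_matrix.z is None:
        raise ValueError("z matrix not filled; call fisher_z first")
    n = z_matrix.n_nodes
    iu, ju = np.triu_indices(n, k=1)
    C = z_matrix.z[iu, ju]
    G = curves.global_auc.reindex(GLOBAL_METRIC_NAMES).to_numpy(float)
    N = np.concatenate([curves.nodal_auc[m].to_numpy(float)
                        for m in NODAL_METRIC_NAMES])
    return FeatureBlocks(C=C, G=G, N=N, subject_id=subject_id, group=int(group))


def ttest_pvalues(features: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Two-sided pooled-variance two-sample t-test p-value per column.

    Zero-variance columns get p = 1.
    """
    labels = np.asarray(labels)
    a = features[labels == 1]
    b = features[labels == 0]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 training subjects per class")
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(axis=0, ddof=1) +
           (nb - 1) * b.var(axis=0, ddof=1)) / (na + nb - 2)
    se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(se > 0, (a.mean(axis=0) - b.mean(axis=0)) / se, 0.0)
    return 2.0 * stats.t.sf(np.abs(t), na + nb - 2)


def ttest_select(features: np.ndarray, labels: np.ndarray,
                 alpha: float = 0.05) -> np.ndarray:
    """Indices whose two-sample t-test p < alpha (training data only)."""
    return np.flatnonzero(ttest_pvalues(features, labels) < alpha)


def build_kernel(features: np.ndarray, train_idx: np.ndarray) -> np.ndarray:
    """Trace-normalized linear kernel from train-standardized features.

    Features are z-scored with training-subject statistics only;
    zero-variance training features are dropped. The kernel is scaled so
    the trace of its training block equals the number of training
    subjects.
    """
    X = np.asarray(features, float)
    mu = X[train_idx].mean(axis=0)
    sd = X[train_idx].std(axis=0)
    keep = sd > 0
    if not keep.any():
        return np.zeros((len(X), len(X)))
    Xs = (X[:, keep] - mu[keep]) / sd[keep]
    K = Xs @ Xs.T
    tr = np.trace(K[np.ix_(train_idx, train_idx)])
    if tr > 0:
        K *= len(train_idx) / tr
    return K


def beta_grid(n_blocks: int, step: float = DEFAULT_BETA_STEP) -> list[tuple[float, ...]]:
    """Simplex lattice of kernel weights with the given step."""
    if n_blocks == 1:
        return [(1.0,)]
    levels = int(round(1.0 / step))
    grid = []
    for combo in itertools.product(range(levels + 1), repeat=n_blocks):
        if sum(combo) == levels:
            grid.append(tuple(c / levels for c in combo))
    return sorted(grid)


def mk_svm_train(kernels: list[np.ndarray], betas: tuple[float, ...],
                 labels: np.ndarray, C: float,
                 train_idx: np.ndarray) -> SVC:
    """Soft-margin SVM on the convex kernel combination sum(beta_m K_m).

    Class weights are balanced: leave-one-out training sets of a balanced
    cohort are always imbalanced by one subject, and unweighted SVMs then
    carry a majority-class bias.
    """
    if any(b < 0 for b in betas) or abs(sum(betas) - 1.0) > 1e-9:
        raise ValueError("betas must be nonnegative and sum to 1")
    y = np.asarray(labels)[train_idx]
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    K = _combine(kernels, betas)
    model = SVC(kernel="precomputed", C=C, class_weight="balanced")
    model.fit(K[np.ix_(train_idx, train_idx)], y)
    return model


def _combine(kernels: list[np.ndarray], betas: tuple[float, ...]) -> np.ndarray:
    K = np.zeros_like(kernels[0])
    for b, Km in zip(betas, kernels):
        if b:
            K = K + b * Km
    return K


def balance_training_indices(idx: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Equalize class counts by dropping highest-index surplus subjects.

    Leave-one-out training sets of a balanced cohort are imbalanced by
    one subject, and margin classifiers are not neutral to that
    imbalance: the held-out subject always belongs to the training
    minority class, which biases cross-validated accuracy even for null
    data. Training every fold on an exactly balanced subset removes the
    class-composition signal; the drop rule is deterministic and
    label-blind (ordering only).
    """
    idx = np.asarray(idx)
    members1 = idx[y[idx] == 1]
    members0 = idx[y[idx] == 0]
    k = min(len(members1), len(members0))
    keep = set(members1[:k]) | set(members0[:k])
    return np.array([i for i in idx if i in keep])


def _fit_predict_one(K: np.ndarray, y: np.ndarray, tr: np.ndarray,
                     te: int, C: float) -> int:
    """Fit a balanced C-SVC on K[tr, tr] and predict subject ``te``."""
    K_tr = np.ascontiguousarray(K[np.ix_(tr, tr)])
    K_te = np.ascontiguousarray(K[te, tr][None, :])
    y_tr = y[tr].astype(np.float64)
    if _llsvm is not None:
        counts = np.bincount(y_tr.astype(int), minlength=2)
        cw = len(y_tr) / (2.0 * np.maximum(counts, 1))
        fit = _llsvm.fit(K_tr, y_tr, svm_type=0, kernel="precomputed",
                         C=C, class_weight=cw)
        return int(_llsvm.predict(K_te, *fit[:7], svm_type=0,
                                  kernel="precomputed")[0])
    model = SVC(kernel="precomputed", C=C,
                class_weight="balanced")  # pragma: no cover
    model.fit(K_tr, y_tr)  # pragma: no cover
    return int(model.predict(K_te)[0])  # pragma: no cover


def nested_loocv(cohort_features: list[FeatureBlocks],
                 combo: tuple[str, ...] = ("C", "G", "N"),
                 alpha: float = 0.05,
                 C_grid: tuple[float, ...] = DEFAULT_C_GRID,
                 beta_step: float = DEFAULT_BETA_STEP,
                 seed: int = 0) -> ClassificationResult:
    """Nested leave-one-out cross-validation with per-fold selection.

    Outer loop: hold out one subject; t-test selection (C and N blocks)
    and feature standardizers are refit on the training subjects and used
    for the final fold model and the consensus bookkeeping. Inner loop:
    LOOCV over the training subjects picks (cost C, kernel weights), with
    selection and standardization refit inside every inner fold as well,
    so the inner accuracy honestly ranks hyperparameters; ties break
    toward smaller C, then lexicographically smaller weights. The
    held-out subject never influences selection, scaling, or tuning.
    ``seed`` is accepted for interface uniformity; the procedure is
    deterministic.
    """
    combo = tuple(combo)
    if not combo or any(b not in ("C", "G", "N") for b in combo):
        raise ValueError("combo must be a nonempty subset of C, G, N")
    if len(C_grid) == 0:
        raise ValueError("empty C grid")
    n = len(cohort_features)
    y = np.array([f.group for f in cohort_features])
    if (y == 1).sum() < 3 or (y == 0).sum() < 3:
        raise ValueError("need >= 3 subjects per class for nested LOOCV")
    betas_list = beta_grid(len(combo), beta_step)
    blocks = {b: np.stack([f.block(b) for f in cohort_features]) for b in combo}

    records = []
    selected_C: list[np.ndarray] = []
    selected_N: list[np.ndarray] = []
    fold_pvals_C: list[np.ndarray] = []
    for held in range(n):
        avail = np.array([i for i in range(n) if i != held])
        train_idx = balance_training_indices(avail, y)
        sel: dict[str, np.ndarray] = {}
        for b in combo:
            if b == "G":
                sel[b] = np.arange(blocks[b].shape[1])
            else:
                sel[b] = ttest_select(blocks[b][train_idx], y[train_idx], alpha)
        if "C" in combo:
            selected_C.append(sel["C"])
            fold_pvals_C.append(ttest_pvalues(blocks["C"][train_idx],
                                              y[train_idx]))
        if "N" in combo:
            selected_N.append(sel["N"])
        kernels = [build_kernel(blocks[b][:, sel[b]], train_idx) for b in combo]

        # Inner LOOCV over the (balanced) training subjects: selection,
        # standardization, kernels, and the class-balancing drop are refit
        # with the inner held-out subject excluded, so inner accuracy is
        # an honest generalization estimate for every (C, betas) pair.
        n_tr = len(train_idx)
        y_tr = y[train_idx]
        loc_trs = []
        inner_kernels: list[list[np.ndarray]] = []
        for pos in range(n_tr):
            rest = np.delete(np.arange(n_tr), pos)
            loc_tr = balance_training_indices(rest, y_tr)
            loc_trs.append(loc_tr)
            feats_pos = []
            for b in combo:
                feats_tr = blocks[b][train_idx]
                if b == "G":
                    s = np.arange(feats_tr.shape[1])
                else:
                    s = ttest_select(feats_tr[loc_tr], y_tr[loc_tr], alpha)
                feats_pos.append(build_kernel(feats_tr[:, s], loc_tr))
            inner_kernels.append(feats_pos)

        scored = []
        for betas in betas_list:
            combined = [_combine(ks, betas) for ks in inner_kernels]
            for C in sorted(C_grid):
                hits = sum(
                    _fit_predict_one(combined[pos], y_tr, loc_trs[pos],
                                     pos, C) == y_tr[pos]
                    for pos in range(n_tr))
                scored.append((hits / n_tr, C, betas))
        # One-standard-error rule: among configurations within one binomial
        # SE of the best inner accuracy, prefer the smallest cost C, then
        # the lexicographically smallest weights. Per-fold argmax over
        # near-tied noisy inner scores would otherwise couple the chosen
        # configuration to the fold and bias the outer estimate.
        acc_max = max(s[0] for s in scored)
        tol = np.sqrt(max(acc_max * (1 - acc_max), 1e-12) / n_tr)
        _, C_star, betas_star = min(
            ((a, C, b) for a, C, b in scored if a >= acc_max - tol),
            key=lambda s: (s[1], s[2]))
        model = mk_svm_train(kernels, betas_star, y, C_star, train_idx)
        K_star = _combine(kernels, betas_star)
        row = K_star[held, train_idx][None, :]
        records.append({
            "subject_id": cohort_features[held].subject_id,
            "truth": int(y[held]),
            "prediction": int(model.predict(row)[0]),
            "decision_value": float(model.decision_function(row)[0]),
            "C": float(C_star),
            "betas": betas_star,
            "n_selected_C": len(sel.get("C", [])),
            "n_selected_N": len(sel.get("N", [])),
        })

    folds = pd.DataFrame(records)
    consensus = (consensus_indices(selected_C) if selected_C
                 else np.array([], int))
    summary = performance_summary(folds["prediction"].to_numpy(),
                                  folds["truth"].to_numpy(),
                                  folds["decision_value"].to_numpy())
    summary["n_consensus_connections"] = int(len(consensus))
    if fold_pvals_C:
        mean_p = np.stack(fold_pvals_C).mean(axis=0)
        summary["consensus_mean_p"] = {int(i): float(mean_p[i]) for i in consensus}
    return ClassificationResult(folds=folds, selected_C=selected_C,
                                selected_N=selected_N, consensus_C=consensus,
                                summary=summary, combo=combo)


def consensus_indices(per_fold_selected: list[np.ndarray]) -> np.ndarray:
    """Feature indices selected in every fold (empty fold -> empty set)."""
    if not per_fold_selected:
        return np.array([], int)
    common = set(per_fold_selected[0].tolist())
    for s in per_fold_selected[1:]:
        common &= set(s.tolist())
    return np.array(sorted(common), int)


def consensus_connections(per_fold_selected: list[np.ndarray],
                          node_labels: list[str] | None = None,
                          network_labels: list[str] | None = None,
                          p_summary: dict[int, float] | None = None,
                          n_nodes: int = N_NODES) -> pd.DataFrame:
    """Consensus edge list with node names and network assignments."""
    idx = consensus_indices(per_fold_selected)
    rows = []
    for k in idx:
        i, j = edge_index_to_pair(int(k), n_nodes)
        rows.append({
            "edge_index": int(k),
            "node_i": i, "node_j": j,
            "name_i": node_labels[i - 1] if node_labels else f"node{i:02d}",
            "name_j": node_labels[j - 1] if node_labels else f"node{j:02d}",
            "network_i": network_labels[i - 1] if network_labels else "",
            "network_j": network_labels[j - 1] if network_labels else "",
            "mean_p": float(p_summary[int(k)]) if p_summary else np.nan,
        })
    return pd.DataFrame(rows, columns=["edge_index", "node_i", "node_j",
                                       "name_i", "name_j", "network_i",
                                       "network_j", "mean_p"])


def performance_summary(predictions: np.ndarray, truth: np.ndarray,
                        decision_values: np.ndarray) -> dict:
    """Accuracy / sensitivity / specificity / ROC from per-fold outputs.

    Group 1 (patients) is the positive class; ROC area is the rank
    statistic of the decision values.
    """
    predictions = np.asarray(predictions)
    truth = np.asarray(truth)
    scores = np.asarray(decision_values, float)
    if len(np.unique(truth)) < 2:
        raise ValueError("single-class truth: sensitivity undefined")
    tp = int(((predictions == 1) & (truth == 1)).sum())
    tn = int(((predictions == 0) & (truth == 0)).sum())
    fp = int(((predictions == 1) & (truth == 0)).sum())
    fn = int(((predictions == 0) & (truth == 1)).sum())
    fpr, tpr, _ = roc_curve(truth, scores)
    return {
        "accuracy": (tp + tn) / len(truth),
        "sensitivity": tp / (tp + fn),
        "specificity": tn / (tn + fp),
        "roc_points": list(zip(fpr.tolist(), tpr.tolist())),
        "roc_auc": float(roc_auc_score(truth, scores)),
    }
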