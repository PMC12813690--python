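"""Feature assembly, t-test selection, kernels, MK-SVM, nested LOOCV
contracts, consensus connections, and performance summaries."""

import numpy as np
import pytest

from connectoscope.classify import (DEFAULT_C_GRID, FeatureBlocks,
                                    balance_training_indices, beta_grid,
                                    build_kernel, consensus_connections,
                                    consensus_indices, edge_index_to_pair,
                                    mk_svm_train, nested_loocv,
                                    pair_to_edge_index, performance_summary,
                                    ttest_pvalues, ttest_select)


class TestEdgeIndexing:
    def test_ordering_contract_endpoints(self):
        assert edge_index_to_pair(0) == (1, 2)
        assert edge_index_to_pair(4004) == (89, 90)
        assert pair_to_edge_index(1, 2) == 0
        assert pair_to_edge_index(89, 90) == 4004

    def test_round_trip_bijection(self):
        for k in range(4005):
            i, j = edge_index_to_pair(k)
            assert pair_to_edge_index(i, j) == k

    def test_out_of_range_rejected(self):
        with pytest.raises(IndexError):
            edge_index_to_pair(4005)
        with pytest.raises(IndexError):
            pair_to_edge_index(2, 2)


class TestTtestSelect:
    def test_alpha_one_selects_everything(self, rng):
        X = rng.standard_normal((20, 50))
        y = np.array([1] * 10 + [0] * 10)
        assert len(ttest_select(X, y, alpha=1.0)) == 50

    def test_strong_feature_always_selected(self, rng):
        y = np.array([1] * 25 + [0] * 25)
        hits = 0
        for seed in range(50):
            r = np.random.default_rng(seed)
            X = r.standard_normal((50, 30))
            X[y == 1, 0] += 3.0  # three pooled sd apart
            hits += int(0 in ttest_select(X, y, 0.05))
        assert hits >= 49

    def test_null_selection_rate_near_alpha(self, rng):
        y = np.array([1] * 20 + [0] * 20)
        rates = [len(ttest_select(np.random.default_rng(s).standard_normal(
            (40, 400)), y, 0.05)) / 400 for s in range(30)]
        assert np.mean(rates) == pytest.approx(0.05, abs=0.01)

    def test_matches_scipy_pvalues(self, rng):
        from scipy import stats
        X = rng.standard_normal((30, 25))
        y = np.array([1] * 14 + [0] * 16)
        p = ttest_pvalues(X, y)
        _, p_ref = stats.ttest_ind(X[y == 1], X[y == 0], axis=0)
        assert np.allclose(p, p_ref, atol=1e-12)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            ttest_select(rng.standard_normal((4, 5)), np.ones(4), 0.05)


class TestBuildKernel:
    def test_training_block_trace_equals_n_train(self, rng):
        X = rng.standard_normal((12, 30))
        tr = np.arange(10)
        K = build_kernel(X, tr)
        assert np.trace(K[np.ix_(tr, tr)]) == pytest.approx(10, abs=1e-8)

    def test_kernel_is_symmetric_psd(self, rng):
        K = build_kernel(rng.standard_normal((15, 40)), np.arange(12))
        assert np.allclose(K, K.T)
        assert np.linalg.eigvalsh(K).min() >= -1e-8

    def test_duplicated_subject_duplicates_gram_row(self, rng):
        X = rng.standard_normal((8, 20))
        X[7] = X[0]
        K = build_kernel(X, np.arange(7))
        assert np.allclose(K[7], K[0])

    def test_zero_variance_features_dropped(self, rng):
        X = rng.standard_normal((10, 5))
        X[:8, 2] = 1.0  # constant on the training rows
        K = build_kernel(X, np.arange(8))
        assert np.isfinite(K).all()


class TestBetaGrid:
    def test_simplex_lattice_properties(self):
        grid = beta_grid(3, 0.5)
        assert (0.0, 0.0, 1.0) in grid and (1.0, 0.0, 0.0) in grid
        for betas in grid:
            assert sum(betas) == pytest.approx(1.0)
            assert all(b >= 0 for b in betas)
        assert beta_grid(1) == [(1.0,)]
        assert len(beta_grid(2, 0.1)) == 11


class TestMkSvmTrain:
    def _blocks(self, rng, n=16):
        y = np.array([1] * (n // 2) + [0] * (n // 2))
        X = rng.standard_normal((n, 10)) + 3.0 * y[:, None]
        K1 = build_kernel(X, np.arange(n))
        K2 = build_kernel(rng.standard_normal((n, 10)), np.arange(n))
        return K1, K2, y

    def test_unit_weight_reduces_to_single_kernel(self, rng):
        K1, K2, y = self._blocks(rng)
        tr = np.arange(len(y))
        a = mk_svm_train([K1, K2], (1.0, 0.0), y, 1.0, tr)
        b = mk_svm_train([K1], (1.0,), y, 1.0, tr)
        assert (a.predict(K1[np.ix_(tr, tr)])
                == b.predict(K1[np.ix_(tr, tr)])).all()

    def test_separable_clusters_fit_perfectly(self, rng):
        K1, K2, y = self._blocks(rng)
        tr = np.arange(len(y))
        model = mk_svm_train([K1, K2], (0.5, 0.5), y, 10.0, tr)
        K = 0.5 * K1 + 0.5 * K2
        assert (model.predict(K[np.ix_(tr, tr)]) == y).all()

    def test_kernel_scaling_compensated_by_cost(self, rng):
        K1, K2, y = self._blocks(rng)
        tr = np.arange(len(y))
        a = mk_svm_train([K1], (1.0,), y, 1.0, tr)
        b = mk_svm_train([4.0 * K1], (1.0,), y, 0.25, tr)
        assert (a.predict(K1[np.ix_(tr, tr)])
                == b.predict(4.0 * K1[np.ix_(tr, tr)])).all()

    def test_invalid_weights_rejected(self, rng):
        K1, K2, y = self._blocks(rng)
        with pytest.raises(ValueError):
            mk_svm_train([K1, K2], (0.7, 0.7), y, 1.0, np.arange(len(y)))

    def test_single_class_training_rejected(self, rng):
        K1, _, y = self._blocks(rng)
        with pytest.raises(ValueError):
            mk_svm_train([K1], (1.0,), np.ones_like(y), 1.0, np.arange(len(y)))


def _toy_features(rng, n=12, n_feat=60, delta=2.5):
    y = np.array([1] * (n // 2) + [0] * (n // 2))
    feats = []
    for i in range(n):
        C = rng.standard_normal(n_feat)
        C[:4] += delta * y[i]
        feats.append(FeatureBlocks(
            C=C, G=rng.standard_normal(8), N=rng.standard_normal(20),
            subject_id=f"s{i:02d}", group=int(y[i])))
    return feats


class TestNestedLoocv:
    def test_loocv_contract_each_subject_held_out_once(self, rng):
        feats = _toy_features(rng)
        res = nested_loocv(feats, combo=("C",), C_grid=(1.0,), beta_step=0.5)
        assert len(res.folds) == 12
        assert sorted(res.folds["subject_id"]) == [f.subject_id for f in feats]
        assert len(res.selected_C) == 12

    def test_separable_cohort_classified_accurately(self, rng):
        feats = _toy_features(rng, n=16, delta=4.0)
        res = nested_loocv(feats, combo=("C", "G", "N"),
                           C_grid=(0.125, 1.0, 8.0), beta_step=0.5)
        assert res.summary["accuracy"] >= 0.8
        assert res.summary["roc_auc"] >= 0.85

    def test_corrupting_held_out_subject_cannot_change_its_fold(self, rng):
        """No-leakage property: the held-out subject's features influence
        neither the selected features nor the tuned hyperparameters."""
        feats = _toy_features(rng, n=10)
        res1 = nested_loocv(feats, combo=("C",), C_grid=(0.5, 2.0),
                            beta_step=0.5)
        corrupted = [FeatureBlocks(C=f.C.copy(), G=f.G, N=f.N,
                                   subject_id=f.subject_id, group=f.group)
                     for f in feats]
        corrupted[3].C[:] = 1e3 * rng.standard_normal(len(corrupted[3].C))
        res2 = nested_loocv(corrupted, combo=("C",), C_grid=(0.5, 2.0),
                            beta_step=0.5)
        assert np.array_equal(res1.selected_C[3], res2.selected_C[3])
        assert res1.folds.loc[3, "C"] == res2.folds.loc[3, "C"]
        assert res1.folds.loc[3, "betas"] == res2.folds.loc[3, "betas"]

    @pytest.mark.parametrize("combo", [("C",), ("G",), ("N",), ("C", "G"),
                                       ("C", "N"), ("G", "N"),
                                       ("C", "G", "N")])
    def test_every_block_combination_runs_through_one_engine(self, rng, combo):
        feats = _toy_features(rng, n=12)
        res = nested_loocv(feats, combo=combo, C_grid=(1.0,), beta_step=0.5)
        assert len(res.folds) == 12
        assert res.combo == combo
        assert 0.0 <= res.summary["accuracy"] <= 1.0

    def test_empty_grid_rejected(self, rng):
        with pytest.raises(ValueError):
            nested_loocv(_toy_features(rng), C_grid=())

    def test_balancing_drops_surplus_class_members(self):
        y = np.array([1, 1, 1, 0, 0])
        idx = balance_training_indices(np.arange(5), y)
        assert list(idx) == [0, 1, 3, 4]


class TestConsensus:
    def test_intersection_semantics(self):
        sets = [np.array([1, 2, 3]), np.array([1, 2]), np.array([1, 2, 4])]
        assert consensus_indices(sets).tolist() == [1, 2]
        assert consensus_indices([np.array([1]), np.array([])]).size == 0

    def test_edge_list_annotation(self):
        table = consensus_connections([np.array([0, 4004]),
                                       np.array([0, 4004])],
                                      node_labels=[f"R{k}" for k in range(1, 91)])
        assert list(table["node_i"]) == [1, 89]
        assert list(table["node_j"]) == [2, 90]
        assert list(table["name_i"]) == ["R1", "R89"]


class TestPerformanceSummary:
    def test_contingency_arithmetic(self):
        truth = np.array([1] * 10 + [0] * 10)
        pred = truth.copy()
        pred[8:10] = 0   # 2 false negatives
        pred[10] = 1     # 1 false positive
        scores = pred + 0.1 * np.arange(20)
        s = performance_summary(pred, truth, scores)
        assert s["accuracy"] == pytest.approx(0.85)
        assert s["sensitivity"] == pytest.approx(0.80)
        assert s["specificity"] == pytest.approx(0.90)

    def test_perfect_ordering_gives_unit_auc(self):
        truth = np.array([1, 1, 1, 0, 0, 0])
        s = performance_summary(truth, truth,
                                np.array([3.0, 2.5, 2.0, -1.0, -2.0, -3.0]))
        assert s["roc_auc"] == pytest.approx(1.0)

    def test_random_scores_give_half_auc(self, rng):
        truth = np.tile([1, 0], 100)
        aucs = [performance_summary(truth, truth,
                                    np.random.default_rng(s).standard_normal(200)
                                    )["roc_auc"] for s in range(40)]
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.03)

    def test_single_class_truth_rejected(self):
        with pytest.raises(ValueError):
            performance_summary(np.ones(5), np.ones(5), np.ones(5))
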