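"""Trajectory-preservation metrics: classification, clustering, pseudotime."""

import numpy as np
import pandas as pd
import pytest

from trajselect.containers import ParameterError
from trajselect.evaluate import (
    _nmi_product,
    aggregate_scores,
    cluster_connectivity,
    cluster_nmi,
    dpt_pseudotime,
    kendall_tau,
    knn_classify_cv,
    precision_at_k,
    string_permutation_test,
    svm_eval,
    trajectory_graph_jaccard,
)


class TestPrecisionAtK:
    def test_full_overlap_gives_one(self):
        assert precision_at_k(["a", "b", "c"], {"a", "b", "c", "d"}, 3) == 1.0

    def test_no_overlap_gives_zero(self):
        assert precision_at_k(["a", "b"], {"x", "y"}, 2) == 0.0

    def test_partial(self):
        assert precision_at_k(["a", "b", "c", "d"], {"a", "c"}, 4) == 0.5

    def test_k_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            precision_at_k(["a"], {"a"}, 2)

    def test_nonincreasing_when_reference_is_prefix(self):
        selected = list("abcdefgh")
        reference = {"a", "b", "c"}
        vals = [precision_at_k(selected, reference, k) for k in range(3, 9)]
        assert all(x >= y for x, y in zip(vals, vals[1:]))


class TestKnnClassifyCV:
    def test_separable_blobs_perfect(self, blob_matrix):
        X, labels = blob_matrix
        accs = knn_classify_cv(X, labels, k_clf=3, n_folds=3, seed=0)
        assert np.all(accs == 1.0)

    def test_shuffled_labels_at_chance(self, blob_matrix):
        X, labels = blob_matrix
        accs = []
        for s in range(20):
            shuffled = np.random.default_rng(s).permutation(labels)
            accs.extend(knn_classify_cv(X, shuffled, k_clf=3, n_folds=3, seed=s))
        assert abs(np.mean(accs) - 0.5) < 0.07

    def test_small_class_rejected(self, blob_matrix):
        X, labels = blob_matrix
        labels = labels.copy()
        labels[:2] = 2  # class with 2 members < 3 folds... exactly 2
        with pytest.raises(ParameterError):
            knn_classify_cv(X, labels, n_folds=3)

    def test_selector_refit_per_fold(self, blob_matrix):
        X, labels = blob_matrix
        calls = []

        def selector(train):
            calls.append(train.n_cells)
            return ["f0"]

        accs = knn_classify_cv(X, labels, selector=selector, n_folds=3, seed=0)
        assert len(calls) == 3 and all(c < X.n_cells for c in calls)
        assert np.all(accs == 1.0)


class TestSvmEval:
    def test_separable_classification_perfect(self, blob_matrix):
        X, labels = blob_matrix
        accs = svm_eval(X.values, labels, mode="classify", n_folds=5, seed=0)
        assert np.median(accs) == 1.0

    def test_noiseless_linear_regression_near_exact(self, rng):
        x = rng.uniform(-1, 1, size=(60, 1))
        y = 2.0 * x.ravel() + 0.5
        grid = {"kernel": ["linear"], "C": [1000.0], "epsilon": [1e-4]}
        rmse = svm_eval(x, y, mode="regress", n_folds=5, seed=0, param_grid=grid)
        assert np.median(rmse) < 1e-3

    def test_unknown_mode_rejected(self, rng):
        with pytest.raises(ParameterError):
            svm_eval(rng.normal(size=(10, 2)), np.zeros(10), mode="rank")


class TestNMI:
    def test_identical_partitions(self, blob_matrix):
        X, labels = blob_matrix
        vals = cluster_nmi(X.values[:, [0]], labels, n_clusters=2, n_init=5, seed=0)
        assert np.allclose(vals, 1.0)

    def test_label_permutation_invariance(self):
        u = np.array([0] * 5 + [1] * 5)
        v = 1 - u  # same partition, relabeled
        assert _nmi_product(u, v) == pytest.approx(_nmi_product(u, u))

    def test_hand_contingency_product_denominator(self):
        # contingency [[3,1],[1,3]]: I and H evaluated by entropy arithmetic
        u = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        v = np.array([0, 0, 0, 1, 0, 1, 1, 1])
        joint = np.array([[3, 1], [1, 3]]) / 8.0
        pu = pv = np.array([0.5, 0.5])
        mi = sum(
            joint[i, j] * np.log(joint[i, j] / (pu[i] * pv[j]))
            for i in range(2)
            for j in range(2)
        )
        h = -np.sum(pu * np.log(pu))
        assert _nmi_product(u, v) == pytest.approx(2 * mi / (h * h))

    def test_sum_denominator_matches_sklearn(self):
        from sklearn.metrics import normalized_mutual_info_score

        u = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        v = np.array([0, 0, 0, 1, 0, 1, 1, 1])
        X = np.column_stack([v + 0.0]) * 10  # KMeans with 2 centers recovers v
        vals = cluster_nmi(X, u, n_clusters=2, n_init=3, seed=0, denominator="sum")
        assert vals[0] == pytest.approx(normalized_mutual_info_score(u, v))


class TestPseudotime:
    def test_chain_orders_cells_perfectly(self):
        n = 50
        X = np.linspace(0, 10, n)[:, None] + np.zeros((n, 3))
        pt = dpt_pseudotime(X, root=0, n_comps=10, k=5)
        assert pt[0] == 0.0
        # ordering is exact up to numerical ties in the diffusion spectrum
        assert kendall_tau(pt, np.arange(n)) >= 0.99

    def test_opposite_root_reverses_order(self):
        n = 50
        X = np.linspace(0, 10, n)[:, None] + np.zeros((n, 3))
        pt_end = dpt_pseudotime(X, root=n - 1, n_comps=10, k=5)
        assert kendall_tau(pt_end, np.arange(n)) <= -0.99

    def test_multi_root_shape(self):
        n = 30
        X = np.linspace(0, 5, n)[:, None] + np.zeros((n, 2))
        pts = dpt_pseudotime(X, root=[0, n - 1], n_comps=8, k=5)
        assert pts.shape == (2, n)

    def test_bad_root_rejected(self):
        with pytest.raises(ParameterError):
            dpt_pseudotime(np.zeros((10, 2)), root=10)


class TestKendallTau:
    def test_identical(self):
        assert kendall_tau([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_reversed(self):
        assert kendall_tau([1, 2, 3, 4], [4, 3, 2, 1]) == pytest.approx(-1.0)

    def test_single_swap_pair_count(self):
        # pairs: 6 total, 5 concordant, 1 discordant -> (5-1)/6 = 2/3
        assert kendall_tau([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(2 / 3)


class TestGraphJaccard:
    def test_identical_graphs_zero(self):
        W = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]])
        assert trajectory_graph_jaccard(W, W) == 0.0

    def test_disjoint_edge_sets_one(self):
        A = np.array([[0, 1, 0], [1, 0, 0], [0, 0, 0]])
        B = np.array([[0, 0, 0], [0, 0, 1], [0, 1, 0]])
        assert trajectory_graph_jaccard(A, B) == 1.0

    def test_half_overlap(self):
        A = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]])  # edges ab, bc
        B = np.array([[0, 1, 0], [1, 0, 0], [0, 0, 0]])  # edge ab
        assert trajectory_graph_jaccard(A, B) == pytest.approx(0.5)

    def test_both_empty_zero_by_convention(self):
        Z = np.zeros((3, 3))
        assert trajectory_graph_jaccard(Z, Z) == 0.0

    def test_cluster_connectivity_recovers_chain(self, rng):
        from trajselect.graph import build_affinity_graph

        # three overlapping blobs along a line: expect chain adjacency 0-1-2
        X = np.concatenate(
            [rng.normal(c, 0.5, size=(30, 1)) for c in (0.0, 1.0, 2.0)]
        )
        labels = np.repeat([0, 1, 2], 30)
        G = build_affinity_graph(X, k=5)
        adj = cluster_connectivity(G.weights, labels, threshold=0.1)
        expected = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
        np.testing.assert_array_equal(adj, expected)


class TestStringPermutationTest:
    def test_extreme_enrichment_minimal_p(self, rng):
        d = 30
        assoc = np.zeros((d, d))
        clique = np.arange(5)
        assoc[np.ix_(clique, clique)] = 1.0
        np.fill_diagonal(assoc, 0.0)
        p = string_permutation_test(assoc, clique, R=100, seed=0)
        assert p == pytest.approx(1 / 101)

    def test_null_identical_statistic_p_one(self):
        assoc = np.zeros((10, 10))
        p = string_permutation_test(assoc, np.array([0, 1, 2]), R=50, seed=0)
        assert p == 1.0

    def test_planted_clique_significant(self):
        rng = np.random.default_rng(8)
        d = 100
        assoc = (rng.random((d, d)) < 0.02).astype(float)
        assoc = np.triu(assoc, 1)
        assoc = assoc + assoc.T
        clique = np.arange(8)
        assoc[np.ix_(clique, clique)] = 1.0
        np.fill_diagonal(assoc, 0.0)
        p = string_permutation_test(assoc, clique, R=1000, seed=1)
        assert p <= 0.01

    def test_empty_query_rejected(self):
        with pytest.raises(ParameterError):
            string_permutation_test(np.zeros((5, 5)), np.array([], dtype=int))


class TestAggregateScores:
    def test_hand_min_max_arithmetic(self):
        medians = pd.DataFrame(
            {"ds1": [0.9, 0.5], "ds2": [0.8, 0.6]}, index=["m1", "m2"]
        )
        out = aggregate_scores(medians)
        assert out.loc["m1", "aggregate"] == pytest.approx(1.0)
        assert out.loc["m2", "aggregate"] == pytest.approx(0.0)
        assert out.loc["m1", "rank"] == 1

    def test_affine_rescaling_invariance(self):
        medians = pd.DataFrame(
            {"ds1": [0.9, 0.5, 0.7], "ds2": [0.3, 0.6, 0.4]}, index=["a", "b", "c"]
        )
        scaled = medians * 13.0 + 5.0
        pd.testing.assert_frame_equal(
            aggregate_scores(medians), aggregate_scores(scaled)
        )

    def test_single_method_defined_one(self):
        medians = pd.DataFrame({"ds1": [0.4]}, index=["only"])
        out = aggregate_scores(medians)
        assert out.loc["only", "aggregate"] == 1.0


class TestMetricRanges:
    def test_fuzzed_metrics_stay_in_declared_ranges(self, rng):
        for _ in range(200):
            n = rng.integers(4, 20)
            sel = [f"f{j}" for j in range(n)]
            ref = set(rng.choice(sel, size=rng.integers(1, n), replace=False))
            k = int(rng.integers(1, n + 1))
            assert 0.0 <= precision_at_k(sel, ref, k) <= 1.0
            a, b = rng.normal(size=8), rng.normal(size=8)
            assert -1.0 <= kendall_tau(a, b) <= 1.0
            A = (rng.random((4, 4)) < 0.4).astype(float)
            B = (rng.random((4, 4)) < 0.4).astype(float)
            assert 0.0 <= trajectory_graph_jaccard(A, B) <= 1.0
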