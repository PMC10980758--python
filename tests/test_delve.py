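"""DELVE: Delta matrix, module clustering, permutation test, ranking."""

import numpy as np
import pytest

from trajselect.baselines import laplacian_score_rank
from trajselect.containers import ExpressionMatrix, ParameterError
from trajselect.delve import (
    DELVE,
    EmptySeedError,
    cluster_feature_dynamics,
    delta_matrix,
    delve_rank,
    dynamic_module_test,
    select_dynamic_seed,
)


class TestDeltaMatrix:
    def test_literal_sum_matches_closed_form(self, rng):
        Z = rng.normal(size=(17, 9))
        m = Z.shape[0]
        closed = (m / (m - 1)) * (Z - Z.mean(axis=0, keepdims=True))
        np.testing.assert_allclose(delta_matrix(Z), closed, atol=1e-10)

    def test_literal_sum_matches_loop_oracle(self, rng):
        # evaluate the defining sum term by term
        Z = rng.normal(size=(6, 4))
        m = Z.shape[0]
        acc = np.zeros_like(Z)
        for i in range(m):
            acc += Z - np.outer(np.ones(m), Z[i])
        np.testing.assert_allclose(delta_matrix(Z), acc / (m - 1), atol=1e-12)

    def test_identical_rows_give_zero(self):
        Z = np.tile([1.0, 2.0, 3.0], (8, 1))
        np.testing.assert_allclose(delta_matrix(Z), 0.0, atol=1e-12)

    def test_column_sums_zero(self, rng):
        D = delta_matrix(rng.normal(size=(30, 12)))
        np.testing.assert_allclose(D.sum(axis=0), 0.0, atol=1e-8)

    def test_single_row_rejected(self):
        with pytest.raises(ParameterError):
            delta_matrix(np.ones((1, 3)))


class TestModuleClustering:
    def test_two_pure_profile_groups_separate(self, rng):
        a, b = rng.normal(size=20), rng.normal(size=20) + 5
        Delta = np.column_stack([a] * 10 + [b] * 10)
        labels = cluster_feature_dynamics(Delta, c=2, seed=0)
        assert len(np.unique(labels[:10])) == 1
        assert len(np.unique(labels[10:])) == 1
        assert labels[0] != labels[10]

    def test_c_equals_d_gives_singletons(self, rng):
        Delta = rng.normal(size=(15, 6))
        labels = cluster_feature_dynamics(Delta, c=6, seed=0)
        assert len(np.unique(labels)) == 6

    def test_c_exceeding_d_rejected(self, rng):
        with pytest.raises(ParameterError):
            cluster_feature_dynamics(rng.normal(size=(10, 4)), c=5)

    def test_structured_profiles_recovered_above_chance(self):
        """Sinusoidal profiles vs white noise: clustering should agree with
        the ground truth at least as well as shuffled labels do."""
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(3)
        t = np.linspace(0, 4 * np.pi, 50)
        sines = np.column_stack([np.sin(t + ph) for ph in rng.uniform(0, 0.3, 20)])
        noise = rng.normal(size=(50, 80))
        Delta = np.column_stack([sines, noise])
        truth = np.r_[np.zeros(20, dtype=int), np.ones(80, dtype=int)]
        wins = 0
        for s in range(20):
            labels = cluster_feature_dynamics(Delta, c=2, seed=s)
            shuffled = np.random.default_rng(s).permutation(labels)
            if adjusted_rand_score(truth, labels) >= adjusted_rand_score(truth, shuffled):
                wins += 1
        assert wins >= 18


class TestDynamicModuleTest:
    def test_constant_cluster_never_dynamic(self, rng):
        Delta = np.column_stack([np.zeros((40, 5)), rng.normal(size=(40, 15))])
        labels = np.r_[np.zeros(5, dtype=int), np.ones(15, dtype=int)]
        table = dynamic_module_test(Delta, labels, t=200, seed=0)
        assert not table.loc[0, "dynamic"]

    def test_high_vs_low_variance_clusters(self, rng):
        """High-variance module flagged dynamic, near-constant module not,
        checked against directly computed variances."""
        lo = rng.normal(0, 0.01, size=(60, 10))
        hi = rng.normal(0, 3.0, size=(60, 10))
        Delta = np.column_stack([lo, hi])
        labels = np.r_[np.zeros(10, dtype=int), np.ones(10, dtype=int)]
        table = dynamic_module_test(Delta, labels, t=100, seed=1)
        assert not table.loc[0, "dynamic"] and table.loc[1, "dynamic"]
        np.testing.assert_allclose(
            table.loc[1, "cluster_variance"],
            Delta[:, 10:].var(axis=0, ddof=1).mean(),
            rtol=1e-12,
        )

    def test_null_calibration_near_half(self):
        """Exchangeable noise features: each module beats its permutation
        null about half the time (no systematic pass)."""
        flags = []
        for s in range(30):
            rng = np.random.default_rng(1000 + s)
            Delta = rng.normal(size=(30, 40))
            labels = rng.integers(0, 4, size=40)
            if len(np.unique(labels)) < 4:
                continue
            table = dynamic_module_test(Delta, labels, t=300, seed=s)
            flags.extend(table["dynamic"].tolist())
        rate = np.mean(flags)
        assert 0.3 <= rate <= 0.7

    def test_empty_label_vector_mismatch(self, rng):
        with pytest.raises(Exception):
            dynamic_module_test(rng.normal(size=(10, 5)), np.zeros(4, dtype=int))


def _structured_matrix(rng, n=120, d=40, n_dyn=10):
    """Cells along a 1-D gradient; first n_dyn features track it, rest noise."""
    t = np.linspace(0, 1, n)
    signal = np.column_stack([np.sin(2 * np.pi * (t + ph)) for ph in rng.uniform(0, 0.2, n_dyn)])
    noise = rng.normal(0, 0.4, size=(n, d - n_dyn))
    X = np.column_stack([signal + rng.normal(0, 0.05, size=signal.shape), noise])
    return ExpressionMatrix(
        X, [f"c{i}" for i in range(n)], [f"f{j}" for j in range(d)], "normalized"
    )


class TestSeedSelection:
    def test_dynamic_features_recovered_on_structured_data(self, rng):
        X = _structured_matrix(rng)
        result = select_dynamic_seed(X, k=10, m=60, c=2, t=200, n_runs=5, seed=0)
        seed_set = set(result.seed_features)
        assert seed_set  # nonempty
        dyn_truth = {f"f{j}" for j in range(10)}
        assert len(seed_set & dyn_truth) / len(seed_set) >= 0.8

    def test_pure_noise_yields_small_seed(self):
        """Negative control: on exchangeable i.i.d. noise the dynamic seed
        must stay a small minority of features. (It is rarely exactly empty:
        KMeans groups the empirically highest-variance noise features, and
        that selection effect lets one cluster beat the permutation null.)"""
        for s in range(5):
            rng = np.random.default_rng(400 + s)
            X = ExpressionMatrix(
                rng.normal(size=(80, 60)),
                [f"c{i}" for i in range(80)],
                [f"f{j}" for j in range(60)],
                "normalized",
            )
            result = select_dynamic_seed(X, k=8, m=40, c=3, t=100, n_runs=8, seed=s)
            assert len(result.seed_features) <= 0.25 * X.n_features

    def test_module_table_long_format(self, rng):
        X = _structured_matrix(rng)
        result = select_dynamic_seed(X, k=10, m=60, c=2, t=50, n_runs=3, seed=0)
        frame = result.to_frame()
        assert len(frame) == 3 * X.n_features
        assert set(frame.columns) == {"feature_id", "run", "module", "dynamic_flag"}


class TestDelveRank:
    def test_all_features_seed_reduces_to_laplacian_baseline(self, rng):
        X = _structured_matrix(rng)
        ranking = delve_rank(X, list(X.feature_ids), k=10, seed=0)
        baseline = laplacian_score_rank(X, k=10, seed=0)
        assert ranking.order == baseline.order
        np.testing.assert_allclose(ranking.scores, baseline.scores, atol=1e-10)

    def test_order_is_permutation(self, rng):
        X = _structured_matrix(rng)
        ranking = delve_rank(X, [f"f{j}" for j in range(10)], k=10)
        assert sorted(ranking.order) == sorted(X.feature_ids)

    def test_empty_seed_raises_with_guidance(self, rng):
        X = _structured_matrix(rng)
        with pytest.raises(EmptySeedError, match="lower c or raise t"):
            delve_rank(X, [], k=10)

    def test_unknown_seed_feature_rejected(self, rng):
        X = _structured_matrix(rng)
        with pytest.raises(Exception):
            delve_rank(X, ["nope"], k=10)

    def test_noise_columns_leave_original_scores_unchanged(self, rng):
        """Appending pure-noise features must not move the scores of the
        original features once the same dynamic seed is used."""
        X = _structured_matrix(rng)
        seed_feats = [f"f{j}" for j in range(10)]
        base = delve_rank(X, seed_feats, k=10, seed=0)
        extra = np.column_stack([X.values, rng.normal(size=(X.n_cells, 5))])
        X2 = ExpressionMatrix(
            extra,
            list(X.cell_ids),
            list(X.feature_ids) + [f"noise{j}" for j in range(5)],
            "normalized",
        )
        expanded = delve_rank(X2, seed_feats, k=10, seed=0)
        base_scores = dict(zip(base.order, base.scores))
        exp_scores = dict(zip(expanded.order, expanded.scores))
        for f in X.feature_ids:
            assert exp_scores[f] == pytest.approx(base_scores[f], abs=1e-10)


class TestDelveModel:
    def test_fit_is_deterministic(self, rng):
        X = _structured_matrix(rng)
        model = DELVE(X, k=10, m=60, c=2, t=100, n_runs=4)
        r1, r2 = model.fit(seed=7), model.fit(seed=7)
        assert r1.ranking.order == r2.ranking.order
        np.testing.assert_array_equal(r1.ranking.scores, r2.ranking.scores)
        assert r1.seed_features == r2.seed_features

    def test_precision_beats_random_expectation(self, rng):
        X = _structured_matrix(rng)
        res = DELVE(X, k=10, m=60, c=2, t=200, n_runs=5).fit(seed=0)
        top = res.top(10)
        hits = len(set(top) & {f"f{j}" for j in range(10)})
        assert hits / 10 > 10 / 40  # random expectation = dynamic fraction

    def test_summary_mentions_seed_size(self, rng):
        X = _structured_matrix(rng)
        res = DELVE(X, k=10, m=60, c=2, t=100, n_runs=3).fit(seed=0)
        text = res.summary()
        assert "dynamic seed" in text and str(X.n_features) in text
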