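"""Envirotyping: standardization, kernel, clustering, classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import fastmet as fm


class TestZscore:
    def test_hand_example(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        out = fm.zscore_standardize(df)
        np.testing.assert_allclose(out["a"], [-1.0, 0.0, 1.0])

    def test_idempotence(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(20, 3)), columns=list("abc"))
        once = fm.zscore_standardize(df)
        twice = fm.zscore_standardize(once)
        np.testing.assert_allclose(once.to_numpy(), twice.to_numpy(), atol=1e-12)

    def test_constant_column_named_in_error(self):
        df = pd.DataFrame({"ok": [1.0, 2.0], "flat": [3.0, 3.0]})
        with pytest.raises(ValueError, match="flat"):
            fm.zscore_standardize(df)

    def test_missing_values_rejected(self):
        df = pd.DataFrame({"a": [1.0, np.nan]})
        with pytest.raises(ValueError, match="missing"):
            fm.zscore_standardize(df)


class TestCollinearityFilter:
    def test_identical_columns_one_dropped(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=30)
        W = pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=30)})
        reduced, dropped = fm.filter_collinear(W, 0.9)
        assert len(dropped) == 1 and dropped[0] in {"a", "b"}
        assert "c" in reduced.columns

    def test_orthogonal_columns_untouched(self):
        W = pd.DataFrame(np.eye(4), columns=list("abcd"))
        reduced, dropped = fm.filter_collinear(W, 0.9)
        assert dropped == []
        assert list(reduced.columns) == list("abcd")

    def test_single_high_pair_drops_exactly_one(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=100)
        W = pd.DataFrame({
            "a": x,
            "b": 0.99 * x + 0.05 * rng.normal(size=100),
            "c": rng.normal(size=100),
        })
        reduced, dropped = fm.filter_collinear(W, 0.9)
        assert len(dropped) == 1 and dropped[0] in {"a", "b"}
        assert reduced.shape[1] == 2


class TestKernel:
    def test_identity_rows(self):
        W = pd.DataFrame(np.eye(2), index=["a", "b"])
        np.testing.assert_allclose(fm.build_kernel(W).KE.to_numpy(), np.eye(2))

    def test_duplicate_rows(self):
        W = pd.DataFrame([[1.0, 0.0], [1.0, 0.0]], index=["a", "b"])
        np.testing.assert_allclose(fm.build_kernel(W).KE.to_numpy(),
                                   np.ones((2, 2)))

    @given(n=st.integers(3, 12), p=st.integers(2, 6), seed=st.integers(0, 99))
    @settings(max_examples=25, deadline=None)
    def test_trace_and_psd(self, n, p, seed):
        rng = np.random.default_rng(seed)
        W = pd.DataFrame(rng.normal(size=(n, p)))
        KE = fm.build_kernel(W).KE.to_numpy()
        assert np.trace(KE) == pytest.approx(n, abs=1e-8)
        assert np.linalg.eigvalsh(KE).min() >= -1e-8

    def test_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            fm.build_kernel(pd.DataFrame(np.zeros((3, 2))))


class TestUPGMA:
    def test_hand_merge_heights(self):
        D = pd.DataFrame([[0, 1, 4], [1, 0, 5], [4, 5, 0.0]],
                         index=list("ABC"), columns=list("ABC"))
        res = fm.upgma_cluster(D, k=2)
        np.testing.assert_allclose(res.heights, [1.0, 4.5])
        assert res.labels["A"] == res.labels["B"] != res.labels["C"]

    def test_two_points(self):
        D = np.array([[0.0, 2.5], [2.5, 0.0]])
        res = fm.upgma_cluster(D)
        np.testing.assert_allclose(res.heights, [2.5])

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            fm.upgma_cluster(np.zeros((1, 1)))

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError):
            fm.upgma_cluster(np.array([[0.0, 1.0], [2.0, 0.0]]))


class TestElbow:
    def test_three_separated_clusters(self):
        ft = fm.simulate_environment_covariates(30, 10, n_mega=3,
                                                separation=10, seed=4)
        W = fm.zscore_standardize(ft.features)
        assert fm.elbow_k(W.to_numpy(), 6, seed=0) == 3

    def test_single_blob_gives_one(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, 5))
        assert fm.elbow_k(X, 6, seed=0) == 1

    def test_degenerate_sizes_run(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(5, 2))
        assert fm.elbow_k(X, 4, seed=0) >= 1


class TestPCA:
    def test_dominant_direction(self):
        rng = np.random.default_rng(7)
        base = rng.normal(size=50)
        W = pd.DataFrame({
            "a": 10 * base, "b": 10 * base + 0.5 * rng.normal(size=50),
            "c": rng.normal(size=50) * 0.5,
        })
        res = fm.pca_project(fm.zscore_standardize(W))
        assert res.var_explained[0] > 0.6
        assert res.var_explained.sum() == pytest.approx(1.0)

    def test_rotation_invariance_of_shares(self):
        rng = np.random.default_rng(8)
        W = rng.normal(size=(40, 4)) * [3.0, 2.0, 1.0, 0.5]
        Q, _ = np.linalg.qr(rng.normal(size=(4, 4)))
        s1 = fm.pca_project(pd.DataFrame(W)).var_explained
        s2 = fm.pca_project(pd.DataFrame(W @ Q)).var_explained
        np.testing.assert_allclose(s1, s2, atol=1e-10)

    def test_projection_matches_training_scores(self):
        rng = np.random.default_rng(9)
        W = pd.DataFrame(rng.normal(size=(20, 5)))
        res = fm.pca_project(W)
        np.testing.assert_allclose(res.project(W).to_numpy(),
                                   res.scores.to_numpy(), atol=1e-10)


class TestClassifier:
    def test_well_separated_clusters_high_accuracy(self):
        ft = fm.simulate_environment_covariates(60, 10, n_mega=3,
                                                separation=8, seed=11)
        W = fm.zscore_standardize(ft.features)
        pca = fm.pca_project(W)
        clf = fm.train_megaenv_classifier(pca.scores.iloc[:, :3],
                                          ft.true_mega, seed=12)
        assert clf.test_accuracy >= 0.95

    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(13)
        ft = fm.simulate_environment_covariates(90, 10, n_mega=3,
                                                separation=8, seed=13)
        W = fm.zscore_standardize(ft.features)
        pca = fm.pca_project(W)
        permuted = pd.Series(rng.permutation(ft.true_mega.to_numpy()),
                             index=ft.true_mega.index)
        clf = fm.train_megaenv_classifier(pca.scores.iloc[:, :3], permuted,
                                          seed=14)
        assert abs(clf.test_accuracy - 1 / 3) < 0.25

    def test_single_class_trivial(self):
        rng = np.random.default_rng(15)
        pcs = pd.DataFrame(rng.normal(size=(10, 3)))
        labels = pd.Series(np.ones(10, dtype=int), index=pcs.index)
        clf = fm.train_megaenv_classifier(pcs, labels, seed=1)
        assert clf.test_accuracy == 1.0

    def test_missing_training_class_raises(self):
        rng = np.random.default_rng(16)
        pcs = pd.DataFrame(rng.normal(size=(10, 3)), index=list("abcdefghij"))
        labels = pd.Series([1] * 9 + [2], index=pcs.index)
        with pytest.raises(ValueError, match="absent from the training"):
            fm.train_megaenv_classifier(pcs, labels, train_index=list("abcdefghi")[:5])


class TestPipeline:
    def test_recovers_planted_structure(self):
        from sklearn.metrics import adjusted_rand_score

        ft = fm.simulate_environment_covariates(60, 37, n_mega=3,
                                                separation=8, seed=21)
        mea = fm.delineate_mega_environments(ft.features, k_max=8, seed=22)
        assert mea.n_clusters == 3
        assert adjusted_rand_score(ft.true_mega, mea.labels) >= 0.9

    def test_environment_order_invariance(self):
        from sklearn.metrics import adjusted_rand_score

        ft = fm.simulate_environment_covariates(40, 12, n_mega=3,
                                                separation=8, seed=23)
        mea1 = fm.delineate_mega_environments(ft.features, k_max=6, seed=24)
        shuffled = ft.features.sample(frac=1.0, random_state=3)
        mea2 = fm.delineate_mega_environments(shuffled, k_max=6, seed=24)
        common = ft.features.index
        assert adjusted_rand_score(mea1.labels[common], mea2.labels[common]) >= 0.9
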