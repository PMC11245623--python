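"""Similarity matrices, z-normalization, regularized LDA, tournament."""

import numpy as np
import pytest

from carposort.icp_registration import icp
from carposort.similarity_classifier import (
    apply_normalizer,
    build_test_matrix,
    build_train_matrix,
    fit_normalizer,
    lda_fit,
    lda_predict,
    run_session,
    tournament,
)
from carposort.synthetic_seeds import PointCloud


def _random_cloud(n, seed, offset=0.0):
    rng = np.random.default_rng(seed)
    return PointCloud(rng.normal(size=(n, 3)) + offset)


@pytest.fixture(scope="module")
def small_clouds():
    return [_random_cloud(60, s) for s in range(5)]


class TestSimilarityMatrices:
    def test_train_matrix_matches_independent_icp(self, small_clouds):
        M = build_train_matrix(small_clouds)
        assert M.shape == (5, 5)
        assert np.all(np.diag(M) == 0.0)
        for i, j in [(0, 1), (2, 4), (3, 0)]:
            assert M[i, j] == icp(small_clouds[i], small_clouds[j]).mse

    def test_identical_clouds_give_zero_offdiagonal(self):
        c = _random_cloud(50, 9)
        M = build_train_matrix([c, c])
        assert M[0, 1] < 1e-12 and M[1, 0] < 1e-12

    def test_test_matrix_matches_independent_icp(self, small_clouds):
        test, train = small_clouds[:2], small_clouds[2:]
        M = build_test_matrix(test, train)
        assert M.shape == (2, 3)
        assert M[1, 2] == icp(test[1], train[2]).mse

    def test_test_equals_train_recomputes_near_zero_diagonal(self, small_clouds):
        M_train = build_train_matrix(small_clouds)
        M_test = build_test_matrix(small_clouds, small_clouds)
        off = ~np.eye(5, dtype=bool)
        assert np.allclose(M_test[off], M_train[off])
        assert np.all(np.diag(M_test) < 1e-12)

    def test_too_few_clouds_rejected(self, small_clouds):
        with pytest.raises(ValueError):
            build_train_matrix(small_clouds[:1])
        with pytest.raises(ValueError):
            build_test_matrix([], small_clouds)


class TestNormalizer:
    def test_train_columns_standardized(self):
        rng = np.random.default_rng(0)
        M = rng.random((20, 6)) * 5
        params = fit_normalizer(M)
        Z = apply_normalizer(M, params)
        assert np.abs(Z.mean(axis=0)).max() < 1e-9
        assert np.abs(Z.std(axis=0) - 1.0).max() < 1e-9

    def test_constant_column_maps_to_zeros(self):
        M = np.column_stack([np.full(10, 3.0), np.arange(10.0)])
        Z = apply_normalizer(M, fit_normalizer(M))
        assert np.all(Z[:, 0] == 0.0)

    def test_test_rows_share_train_parameters(self):
        rng = np.random.default_rng(1)
        train = rng.random((15, 4))
        params = fit_normalizer(train)
        Z_train = apply_normalizer(train, params)
        Z_test = apply_normalizer(train[3:4], params)
        assert np.allclose(Z_test, Z_train[3:4])


class TestLda:
    def test_separable_clusters_perfect_training_accuracy(self):
        rng = np.random.default_rng(0)
        X = np.vstack(
            [rng.normal(0, 0.1, (20, 10)), rng.normal(5, 0.1, (20, 10))]
        )
        y = np.array([0] * 20 + [1] * 20)
        model = lda_fit(X, y)
        assert np.mean(lda_predict(model, X) == y) == 1.0

    def test_held_out_accuracy_on_separated_clusters(self):
        rng = np.random.default_rng(1)
        centers = rng.normal(0, 4.0, (4, 12))
        X_tr = np.vstack([c + rng.normal(0, 0.5, (25, 12)) for c in centers])
        y_tr = np.repeat(np.arange(4), 25)
        X_te = np.vstack([c + rng.normal(0, 0.5, (25, 12)) for c in centers])
        y_te = np.repeat(np.arange(4), 25)
        model = lda_fit(X_tr, y_tr)
        assert np.mean(lda_predict(model, X_te) == y_te) >= 0.95

    def test_permuted_labels_give_chance_training_accuracy(self):
        """With permuted labels the fit finds no structure beyond chance."""
        rng = np.random.default_rng(2)
        X = rng.normal(size=(2000, 3))
        y = np.array([0, 1] * 1000)
        rng.shuffle(y)
        model = lda_fit(X, y)
        acc = np.mean(lda_predict(model, X) == y)
        # chance 0.5; 3 sigma binomial on n=2000 is 0.034, plus a small
        # allowance for in-sample fitting of 3 free directions
        assert abs(acc - 0.5) <= 0.05

    def test_projection_dimension_is_classes_minus_one(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(50, 8))
        y = np.repeat(np.arange(5), 10)
        model = lda_fit(X, y)
        assert model.scalings.shape == (8, 4)
        assert model.centroids.shape == (5, 4)

    def test_tie_broken_toward_first_label(self):
        X = np.array([[-1.0], [-1.0], [1.0], [1.0]])
        y = np.array(["a", "a", "b", "b"])
        model = lda_fit(X, y, gamma=1e-6)
        assert lda_predict(model, np.array([[0.0]]))[0] == "a"

    def test_agrees_with_sklearn_on_well_conditioned_data(self):
        sklearn_lda = pytest.importorskip(
            "sklearn.discriminant_analysis"
        ).LinearDiscriminantAnalysis
        rng = np.random.default_rng(4)
        X = np.vstack(
            [rng.normal(m, 1.0, (40, 5)) for m in ((0, 0, 0, 0, 0), (2, 1, 0, -1, 2), (-2, 2, 1, 0, -1))]
        )
        y = np.repeat(np.arange(3), 40)
        mine = lda_predict(lda_fit(X, y, gamma=1e-9), X)
        ref = sklearn_lda(solver="eigen").fit(X, y).predict(X)
        assert np.mean(mine == ref) >= 0.98

    def test_input_validation(self):
        X = np.random.default_rng(0).normal(size=(10, 3))
        with pytest.raises(ValueError):
            lda_fit(X, np.zeros(10))  # single class
        with pytest.raises(ValueError):
            lda_fit(X, np.arange(10) % 2, gamma=-1.0)
        model = lda_fit(X, np.arange(10) % 2)
        with pytest.raises(ValueError):
            lda_predict(model, np.zeros((2, 7)))


def _shaped_cloud(n, seed, axes=(1.0, 1.0, 1.0)):
    # ICP removes rigid offsets, so classes must differ in shape, not position
    rng = np.random.default_rng(seed)
    return PointCloud(rng.normal(size=(n, 3)) * np.asarray(axes))


@pytest.fixture(scope="module")
def labeled_pools():
    """Two well-separated synthetic 'varieties' as tiny cloud pools."""
    train = [_shaped_cloud(60, s) for s in range(4)] + [
        _shaped_cloud(60, 10 + s, axes=(2.5, 1.0, 0.6)) for s in range(4)
    ]
    train_labels = ["a"] * 4 + ["b"] * 4
    test = [_shaped_cloud(60, 20 + s) for s in range(3)]
    test_labels = ["a"] * 3
    return train, train_labels, test, test_labels


class TestTournament:
    def test_separable_single_class_test_pool(self, labeled_pools):
        train, yl, test, yt = labeled_pools
        res = tournament(train, yl, test, yt, n_sessions=3, rng_seed=0)
        assert res.accumulative_accuracy == 1.0

    def test_single_session_equals_run_session(self, labeled_pools):
        train, yl, test, yt = labeled_pools
        res = tournament(
            train, yl, test, yt, n_sessions=1, rng_seed=5, train_fraction=1.0
        )
        tt = build_train_matrix(train)
        st = build_test_matrix(test, train)
        acc, conf, _ = run_session(tt, np.asarray(yl), st, np.asarray(yt))
        assert res.per_session_accuracy == (acc,)
        assert res.confusion.values.tolist() == conf.values.tolist()

    def test_cached_and_recomputed_sessions_identical(self, labeled_pools):
        train, yl, test, yt = labeled_pools
        kwargs = dict(n_sessions=3, rng_seed=11, train_fraction=0.8)
        cached = tournament(train, yl, test, yt, **kwargs)
        direct = tournament(train, yl, test, yt, use_cache=False, **kwargs)
        assert cached.per_session_accuracy == direct.per_session_accuracy
        assert cached.confusion.equals(direct.confusion)

    def test_confusion_conserves_classifications(self, labeled_pools):
        train, yl, test, yt = labeled_pools
        res = tournament(train, yl, test, yt, n_sessions=4, rng_seed=2)
        assert res.confusion.values.sum() == len(test) * 4

    def test_reproducible_from_seed(self, labeled_pools):
        train, yl, test, yt = labeled_pools
        a = tournament(train, yl, test, yt, n_sessions=2, rng_seed=3)
        b = tournament(train, yl, test, yt, n_sessions=2, rng_seed=3)
        assert a.per_session_accuracy == b.per_session_accuracy

    def test_rejects_single_class_training(self, labeled_pools):
        train, _, test, yt = labeled_pools
        with pytest.raises(ValueError):
            tournament(train, ["a"] * 8, test, yt, n_sessions=1, rng_seed=0)
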