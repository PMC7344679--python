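import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.cross_decomposition import PLSRegression

from sensomet.spls import (
    CVResult,
    SPLSError,
    compute_vip,
    fit_spls,
    fit_splsda,
    grid_search,
    soft_threshold_keep,
)


def dense_pls_oracle(X, Y, ncomp):
    """Independent dense-PLS oracle: exact SVD of each deflated
    cross-covariance matrix, textbook regression-mode deflation."""
    Y = Y[:, None] if Y.ndim == 1 else Y
    xm, xs = X.mean(0), X.std(0, ddof=1)
    ym, ys = Y.mean(0), Y.std(0, ddof=1)
    Xd, Yd = (X - xm) / xs, (Y - ym) / ys
    W, P, Q = [], [], []
    for _ in range(ncomp):
        U, _, _ = np.linalg.svd(Xd.T @ Yd, full_matrices=False)
        u = U[:, 0]
        t = Xd @ u
        tt = t @ t
        p_, q_ = Xd.T @ t / tt, Yd.T @ t / tt
        Xd, Yd = Xd - np.outer(t, p_), Yd - np.outer(t, q_)
        W.append(u), P.append(p_), Q.append(q_)
    W, P, Q = np.array(W).T, np.array(P).T, np.array(Q).T
    B = W @ np.linalg.solve(P.T @ W, Q.T)
    return lambda Xn: ((Xn - xm) / xs) @ B * ys + ym


class TestDenseEquivalence:
    @pytest.mark.parametrize("seed", range(10))
    def test_keepx_p_equals_dense_pls(self, seed):
        rng = np.random.default_rng(seed)
        n, p, q = int(rng.integers(15, 40)), int(rng.integers(5, 30)), int(rng.choice([1, 1, 2]))
        X = rng.standard_normal((n, p))
        Y = X @ rng.standard_normal((p, q)) + 0.5 * rng.standard_normal((n, q))
        ncomp = int(rng.integers(1, min(n - 1, p, 5) + 1))
        m = fit_spls(X, Y, ncomp, keepX=p)
        oracle = dense_pls_oracle(X, Y, ncomp)
        np.testing.assert_allclose(m.predict(X), oracle(X), atol=1e-8)

    def test_univariate_matches_sklearn_pls(self):
        rng = np.random.default_rng(11)
        X = rng.standard_normal((30, 12))
        y = X @ rng.standard_normal(12) + rng.standard_normal(30)
        m = fit_spls(X, y, 3, keepX=12)
        sk = PLSRegression(n_components=3, tol=1e-14).fit(X, y[:, None])
        np.testing.assert_allclose(m.predict(X), sk.predict(X), atol=1e-8)

    def test_first_component_weight_proportional_to_xty(self):
        rng = np.random.default_rng(12)
        X = rng.standard_normal((25, 8))
        y = X @ rng.standard_normal(8) + rng.standard_normal(25)
        m = fit_spls(X, y, 1, keepX=8)
        Xs = (X - X.mean(0)) / X.std(0, ddof=1)
        ys = (y - y.mean()) / y.std(ddof=1)
        w = Xs.T @ ys
        w /= np.linalg.norm(w)
        assert min(
            np.abs(m.x_weights[:, 0] - w).max(),
            np.abs(m.x_weights[:, 0] + w).max(),
        ) < 1e-10


def test_forced_selection_of_identical_column():
    rng = np.random.default_rng(13)
    X = rng.standard_normal((20, 6))
    y = X[:, 3].copy()
    m = fit_spls(X, y, 1, keepX=1)
    assert m.selected_features[0] == [3]
    resid = y - m.predict(X).ravel()
    assert 1 - resid.var() / y.var() == pytest.approx(1.0, abs=1e-10)


class TestSoftThreshold:
    @given(st.integers(1, 19), st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_exact_nonzero_count(self, keep, seed):
        u = np.random.default_rng(seed).standard_normal(20)
        out = soft_threshold_keep(u, keep)
        assert np.count_nonzero(out) == keep
        # survivors are the largest-magnitude entries
        kept = set(np.flatnonzero(out))
        order = np.argsort(-np.abs(u), kind="stable")[:keep]
        assert kept == set(order)

    def test_tie_broken_by_feature_order(self):
        u = np.array([1.0, -1.0, 1.0])
        out = soft_threshold_keep(u, 1)
        assert np.flatnonzero(out).tolist() == [0]

    def test_keep_all_is_identity(self):
        u = np.array([0.3, -0.2, 0.1])
        np.testing.assert_array_equal(soft_threshold_keep(u, 3), u)


class TestVIP:
    def test_closed_form_single_component(self):
        # weights (1, 0, 0), one component -> VIP = (sqrt(3), 0, 0)
        rng = np.random.default_rng(14)
        X = np.column_stack([
            rng.standard_normal(30),
            rng.standard_normal(30),
            rng.standard_normal(30),
        ])
        y = X[:, 0] + 0.01 * rng.standard_normal(30)
        m = fit_spls(X, y, 1, keepX=1)
        np.testing.assert_allclose(m.vip, [np.sqrt(3), 0.0, 0.0], atol=1e-12)

    @pytest.mark.parametrize("ncomp,keepx", [(1, 5), (2, 3), (3, 10)])
    def test_mean_squared_vip_is_one(self, ncomp, keepx):
        rng = np.random.default_rng(15)
        X = rng.standard_normal((25, 10))
        Y = rng.standard_normal((25, 2))
        m = fit_spls(X, Y, ncomp, keepX=keepx)
        assert (m.vip**2).mean() == pytest.approx(1.0, abs=1e-8)

    def test_matches_brute_force_formula(self):
        rng = np.random.default_rng(16)
        X = rng.standard_normal((20, 10))
        Y = rng.standard_normal((20, 2))
        m = fit_spls(X, Y, 2, keepX=4)
        # direct re-evaluation from stored factors
        p = 10
        ssy = np.array([
            (m.y_loadings[:, a] @ m.y_loadings[:, a]) * (m.x_scores[:, a] @ m.x_scores[:, a])
            for a in range(2)
        ])
        wn = m.x_weights / np.linalg.norm(m.x_weights, axis=0)
        expected = np.sqrt(p * (wn**2 @ ssy) / ssy.sum())
        np.testing.assert_allclose(compute_vip(m), expected, atol=1e-12)


class TestSPLSDA:
    def test_linearly_separated_classes_zero_training_error(self):
        rng = np.random.default_rng(17)
        n = 30
        labels = np.array(["a"] * 15 + ["b"] * 15)
        X = rng.standard_normal((n, 5))
        X[:15, 2] += 6.0
        m = fit_splsda(X, labels, 1, keepX=1)
        assert (m.predict_classes(X) == labels).all()
        assert m.selected_features[0] == [2]

    def test_class_with_one_sample_rejected(self):
        X = np.random.default_rng(18).standard_normal((5, 4))
        with pytest.raises(SPLSError, match="fewer than 2"):
            fit_splsda(X, np.array(["a", "a", "a", "a", "b"]), 1, 2)

    def test_single_class_rejected(self):
        X = np.random.default_rng(19).standard_normal((6, 4))
        with pytest.raises(SPLSError, match="2 classes"):
            fit_splsda(X, np.array(["a"] * 6), 1, 2)


class TestValidation:
    def test_keepx_exceeding_features_errors(self):
        X = np.random.default_rng(20).standard_normal((10, 4))
        with pytest.raises(SPLSError, match="keepX"):
            fit_spls(X, X[:, 0], 1, keepX=5)

    def test_rank_bound_errors(self):
        X = np.random.default_rng(21).standard_normal((4, 10))
        with pytest.raises(SPLSError, match="rank"):
            fit_spls(X, X[:, 0], 4, keepX=5)

    def test_zero_variance_column_errors(self):
        X = np.random.default_rng(22).standard_normal((10, 4))
        X[:, 1] = 3.0
        with pytest.raises(SPLSError, match="zero-variance"):
            fit_spls(X, X[:, 0], 1, keepX=2)

    def test_missing_values_imputed_not_fatal(self):
        rng = np.random.default_rng(23)
        X = rng.standard_normal((20, 6))
        X[3, 2] = np.nan
        m = fit_spls(X, X[:, 0], 1, keepX=3)
        assert np.isfinite(m.vip).all()


def test_score_orthogonality_sparse():
    rng = np.random.default_rng(24)
    X = rng.standard_normal((30, 50))
    Y = rng.standard_normal((30, 2))
    m = fit_spls(X, Y, 4, keepX=10)
    G = m.x_scores.T @ m.x_scores
    assert np.abs(G - np.diag(np.diag(G))).max() < 1e-8


class TestGridSearch:
    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(25)
        X = rng.standard_normal((24, 30))
        y = X @ rng.standard_normal(30) + rng.standard_normal(24)
        a = grid_search(X, y, "spls", comp_grid=(1, 2), keepX_grid=(5, 10),
                        n_repeats=3, k=4, seed=7)
        b = grid_search(X, y, "spls", comp_grid=(1, 2), keepX_grid=(5, 10),
                        n_repeats=3, k=4, seed=7)
        assert a.best_pair == b.best_pair
        np.testing.assert_array_equal(
            a.grid["criterion"].to_numpy(), b.grid["criterion"].to_numpy()
        )

    def test_default_grids_match_convention(self):
        # conventional search space: 1..12 components (3 for the
        # discriminant variant) and 50..1000 selected variables
        from sensomet.spls import (
            DEFAULT_COMP_GRID_SPLS,
            DEFAULT_COMP_GRID_SPLSDA,
            DEFAULT_KEEPX_GRID,
        )

        assert DEFAULT_COMP_GRID_SPLS == tuple(range(1, 13))
        assert DEFAULT_COMP_GRID_SPLSDA == (1, 2, 3)
        assert DEFAULT_KEEPX_GRID == (50, 100, 200, 300, 500, 1000)

    def test_single_point_grid_is_best(self):
        rng = np.random.default_rng(26)
        X = rng.standard_normal((20, 10))
        y = X[:, 0] + 0.1 * rng.standard_normal(20)
        cv = grid_search(X, y, "spls", comp_grid=(2,), keepX_grid=(4,),
                         n_repeats=2, k=4, seed=0)
        assert cv.best_pair == (2, 4)
        assert cv.criterion_kind == "q2"

    def test_best_pair_attains_optimum(self):
        rng = np.random.default_rng(27)
        X = rng.standard_normal((24, 15))
        labels = np.repeat(["a", "b", "c"], 8)
        X[labels == "a", 0] += 4
        X[labels == "b", 1] += 4
        cv = grid_search(X, labels, "splsda", comp_grid=(1, 2), keepX_grid=(2, 5),
                         n_repeats=2, k=4, seed=1)
        valid = cv.grid.dropna()
        assert cv.criterion_at(*cv.best_pair) == pytest.approx(valid["criterion"].min())

    def test_keepx_clamped_with_warning(self):
        rng = np.random.default_rng(28)
        X = rng.standard_normal((20, 8))
        y = X[:, 0]
        with pytest.warns(UserWarning, match="clamped"):
            cv = grid_search(X, y, "spls", comp_grid=(1,), keepX_grid=(50,),
                             n_repeats=2, k=4, seed=0)
        assert cv.best_pair == (1, 8)

    def test_folds_exceeding_class_size_error(self):
        rng = np.random.default_rng(29)
        X = rng.standard_normal((12, 5))
        labels = np.array(["a"] * 3 + ["b"] * 9)
        with pytest.raises(SPLSError, match="class size"):
            grid_search(X, labels, "splsda", comp_grid=(1,), keepX_grid=(2,),
                        n_repeats=1, k=5, seed=0)
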