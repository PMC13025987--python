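"""PCA / OPLS-DA properties against independent oracles.

The OPLS-DA fit is cross-checked against a NIPALS PLS1 implementation
written here (and against scikit-learn's PLSRegression) rather than
against itself; VIP normalization, score orthogonality and Q2/R2Y
relations are asserted on every fitted model.
"""

import numpy as np
import pytest

from aromastages import (
    ValidationError,
    autoscale,
    cross_validate_q2,
    fit_oplsda,
    fit_pca,
    permutation_test,
    vip_scores,
)


def nipals_pls1(X, y, tol=1e-12, max_iter=500):
    """Independent one-component PLS1 oracle (textbook NIPALS loop)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    y = y - y.mean()
    u = y.copy()
    w = np.zeros(X.shape[1])
    for _ in range(max_iter):
        w_new = X.T @ u
        w_new /= np.linalg.norm(w_new)
        t = X @ w_new
        c = (y @ t) / (t @ t)
        u_new = y * c
        if np.linalg.norm(w_new - w) < tol:
            w = w_new
            break
        w, u = w_new, u_new
    t = X @ w
    return w, t


def _two_cluster_data(rng, n_per=9, n_vars=30, delta=5.0, n_inf=4):
    X = rng.normal(size=(2 * n_per, n_vars))
    X[n_per:, :n_inf] += delta
    y = [0] * n_per + [1] * n_per
    return X, y


class TestAutoscale:
    def test_two_sample_column_forced_values(self):
        sm = autoscale(np.array([[0.0], [2.0]]), mode="unit_variance")
        np.testing.assert_allclose(sm.X[:, 0], [-1.0, 1.0])

    def test_invariants_and_constant_columns(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 6))
        X[:, 3] = 4.2  # constant
        sm = autoscale(X, mode="unit_variance")
        np.testing.assert_allclose(sm.X.mean(axis=0), 0.0, atol=1e-9)
        sd = sm.X.std(axis=0)
        np.testing.assert_allclose(sd[~sm.constant_mask], 1.0, atol=1e-9)
        assert sm.constant_mask[3]
        np.testing.assert_allclose(sm.X[:, 3], 0.0, atol=1e-12)

    def test_unit_variance_scaling_is_idempotent(self):
        rng = np.random.default_rng(1)
        X = rng.lognormal(size=(8, 5))
        once = autoscale(X, mode="unit_variance")
        twice = autoscale(once.X, mode="unit_variance")
        np.testing.assert_allclose(twice.X, once.X, atol=1e-9)

    def test_pareto_scale_between_center_and_uv(self):
        rng = np.random.default_rng(2)
        X = rng.normal(scale=3.0, size=(20, 4))
        par = autoscale(X, mode="pareto")
        sd = np.asarray(X).std(axis=0)
        np.testing.assert_allclose(par.col_scales, np.sqrt(sd))


class TestPCA:
    def test_rank_one_matrix_explained_by_first_component(self):
        u = np.arange(1.0, 7.0)[:, None]
        v = np.array([[2.0, -1.0, 0.5]])
        sm = autoscale(u @ v, mode="center")
        model = fit_pca(sm, 1)
        assert model.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-9)

    def test_full_rank_reconstruction(self):
        rng = np.random.default_rng(3)
        sm = autoscale(rng.normal(size=(7, 4)), mode="unit_variance")
        model = fit_pca(sm, 4)
        np.testing.assert_allclose(model.reconstruct(), sm.X, atol=1e-8)
        assert (np.diff(model.explained_variance_ratio) <= 1e-12).all()
        gram = model.loadings.T @ model.loadings
        np.testing.assert_allclose(gram, np.eye(4), atol=1e-8)

    def test_duplicated_samples_get_identical_scores(self):
        rng = np.random.default_rng(4)
        base = rng.normal(size=(5, 6))
        X = np.vstack([base, base[2]])
        sm = autoscale(X, mode="unit_variance")
        model = fit_pca(sm, 2)
        np.testing.assert_allclose(model.scores[2], model.scores[5], atol=1e-9)

    def test_too_many_components_rejected(self):
        sm = autoscale(np.random.default_rng(0).normal(size=(4, 3)))
        with pytest.raises(ValidationError):
            fit_pca(sm, 4)


class TestOPLSDA:
    def test_zero_ortho_matches_independent_nipals_pls1(self):
        rng = np.random.default_rng(5)
        X, y = _two_cluster_data(rng)
        sm = autoscale(X)
        model = fit_oplsda(sm, y, n_ortho=0)
        _, t_ref = nipals_pls1(sm.X, y)
        r = np.corrcoef(model.t_pred, t_ref)[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-9)

    def test_zero_ortho_matches_sklearn_pls(self):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        rng = np.random.default_rng(6)
        X, y = _two_cluster_data(rng)
        sm = autoscale(X)
        model = fit_oplsda(sm, y, n_ortho=0)
        pls = sklearn.PLSRegression(n_components=1, scale=False)
        pls.fit(sm.X, np.asarray(y, dtype=float))
        r = np.corrcoef(model.t_pred, pls.x_scores_[:, 0])[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-9)

    def test_separated_clusters_split_by_score_sign(self):
        rng = np.random.default_rng(7)
        X, y = _two_cluster_data(rng, delta=5.0)
        model = fit_oplsda(autoscale(X), y, n_ortho=1)
        signs = np.sign(model.t_pred)
        assert (signs[:9] < 0).all() and (signs[9:] > 0).all()

    def test_label_swap_negates_scores_keeps_fit_quality(self):
        rng = np.random.default_rng(8)
        X, y = _two_cluster_data(rng, delta=2.0)
        sm = autoscale(X)
        m1 = fit_oplsda(sm, y, n_ortho=1)
        m2 = fit_oplsda(sm, [1 - v for v in y], n_ortho=1)
        np.testing.assert_allclose(m1.t_pred, -m2.t_pred, atol=1e-9)
        assert m1.r2y == pytest.approx(m2.r2y, abs=1e-9)
        q1 = cross_validate_q2(sm, y, n_ortho=1, seed=0)
        q2 = cross_validate_q2(sm, [1 - v for v in y], n_ortho=1, seed=0)
        assert q1 == pytest.approx(q2, abs=1e-9)

    def test_model_invariants_on_every_fit(self, default_contents):
        rel, _, samples, _ = default_contents
        ids = [s.sample_id for s in samples
               if s.batch == "F1" and s.stage.value in ("RM", "IF")]
        sub = rel.subset_samples(ids)
        y = [0 if "RM" in i else 1 for i in ids]
        sm = autoscale(sub)
        for n_ortho in (0, 1, 2):
            m = fit_oplsda(sm, y, n_ortho=n_ortho)
            for a in range(m.n_ortho):
                assert abs(m.t_pred @ m.t_ortho[:, a]) <= 1e-8 * (
                    np.linalg.norm(m.t_pred) * np.linalg.norm(m.t_ortho[:, a]))
            assert 0.0 <= m.r2y <= 1.0
            assert np.mean(m.vip ** 2) == pytest.approx(1.0, abs=1e-6)
            q2 = cross_validate_q2(sm, y, n_ortho=n_ortho, seed=1)
            assert q2 <= m.r2y + 1e-9

    def test_deterministic_refit_bit_identical(self):
        rng = np.random.default_rng(9)
        X, y = _two_cluster_data(rng)
        sm = autoscale(X)
        m1 = fit_oplsda(sm, y, n_ortho=1)
        m2 = fit_oplsda(sm, y, n_ortho=1)
        assert (m1.t_pred == m2.t_pred).all()
        assert (m1.vip == m2.vip).all()

    def test_single_class_rejected(self):
        sm = autoscale(np.random.default_rng(0).normal(size=(6, 4)))
        with pytest.raises(ValidationError):
            fit_oplsda(sm, [1, 1, 1, 1, 1, 1])

    def test_excessive_n_ortho_rejected(self):
        sm = autoscale(np.random.default_rng(0).normal(size=(4, 3)))
        with pytest.raises(ValidationError):
            fit_oplsda(sm, [0, 0, 1, 1], n_ortho=5)


class TestVIP:
    def test_single_variable_vip_is_one(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(10, 1))
        y = (X[:, 0] > 0).astype(int)
        m = fit_oplsda(autoscale(X), y, n_ortho=0)
        assert m.vip[0] == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_mean_squared_vip_is_one(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(14, 25))
        y = rng.integers(0, 2, size=14)
        while len(set(y.tolist())) < 2:
            y = rng.integers(0, 2, size=14)
        m = fit_oplsda(autoscale(X), y, n_ortho=1)
        assert np.mean(m.vip ** 2) == pytest.approx(1.0, abs=1e-6)

    def test_planted_informative_variable_has_max_vip(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(16, 20))
        y = np.array([0] * 8 + [1] * 8)
        X[:, 7] += 4.0 * y  # only informative column
        m = fit_oplsda(autoscale(X), y, n_ortho=1)
        assert int(np.argmax(m.vip)) == 7

    def test_unfitted_model_rejected(self):
        rng = np.random.default_rng(12)
        m = fit_oplsda(autoscale(rng.normal(size=(8, 4))), [0, 0, 0, 0, 1, 1, 1, 1])
        m.w_pred = np.empty(0)
        with pytest.raises(ValidationError):
            vip_scores(m)


class TestCrossValidation:
    def test_separable_data_high_q2(self):
        rng = np.random.default_rng(13)
        X, y = _two_cluster_data(rng, n_vars=20, n_inf=10, delta=5.0)
        q2 = cross_validate_q2(autoscale(X), y, n_ortho=1, n_folds=7, seed=0)
        assert q2 > 0.9

    def test_permuted_labels_give_negative_median_q2(self):
        rng = np.random.default_rng(14)
        q2s = []
        for _ in range(20):
            X = rng.normal(size=(16, 20))
            y = rng.permutation([0] * 8 + [1] * 8)
            q2s.append(cross_validate_q2(autoscale(X), y, n_ortho=1, seed=0))
        assert np.median(q2s) < 0.0

    def test_leave_one_out_returns_finite_q2(self):
        rng = np.random.default_rng(15)
        X, y = _two_cluster_data(rng, n_per=4, n_vars=6, delta=3.0)
        q2 = cross_validate_q2(autoscale(X), y, n_folds=8, seed=0)
        assert np.isfinite(q2)

    def test_fold_assignment_deterministic(self):
        rng = np.random.default_rng(16)
        X, y = _two_cluster_data(rng, delta=1.0)
        sm = autoscale(X)
        assert cross_validate_q2(sm, y, seed=5) == cross_validate_q2(sm, y, seed=5)


class TestPermutationTest:
    def test_record_contract_and_add_one_rule(self):
        rng = np.random.default_rng(17)
        X, y = _two_cluster_data(rng, delta=5.0)
        rec = permutation_test(autoscale(X), y, n_perm=50, seed=0)
        assert rec.n_perm == 50
        assert len(rec.q2_permuted) == 50 and len(rec.r2y_permuted) == 50
        assert rec.p_value_q2 >= 1.0 / 51.0

    def test_separated_classes_significant_at_200_perms(self):
        rng = np.random.default_rng(18)
        X, y = _two_cluster_data(rng, n_per=9, delta=5.0)
        rec = permutation_test(autoscale(X), y, n_perm=200, seed=1)
        assert rec.p_value_q2 < 0.05
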