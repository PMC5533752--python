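import numpy as np
import pytest

from nmrmarker import chemometrics as chem


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


class TestScaler:
    def test_pareto_divides_by_sqrt_sd(self, rng):
        X = rng.normal(size=(200, 3))
        X[:, 1] *= 4.0
        sc = chem.SpectralScaler("pareto").fit(X)
        sd = X.std(axis=0, ddof=1)
        np.testing.assert_allclose(sc.scale_, np.sqrt(sd))

    def test_center_mode_scale_is_one(self, rng):
        X = rng.normal(size=(10, 4))
        sc = chem.SpectralScaler("center").fit(X)
        np.testing.assert_array_equal(sc.scale_, np.ones(4))

    def test_scaled_training_columns_have_zero_mean(self, rng):
        X = rng.normal(loc=5.0, size=(30, 6))
        for mode in chem.SpectralScaler.MODES:
            Z = chem.SpectralScaler(mode).fit(X).transform(X)
            np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-10)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError, match="2 rows"):
            chem.SpectralScaler().fit(np.ones((1, 3)))

    def test_zero_sd_columns_dropped(self, rng):
        X = rng.normal(size=(10, 3))
        X[:, 2] = 7.0
        sc = chem.SpectralScaler("pareto").fit(X)
        assert list(sc.dropped_columns_) == [2]
        assert sc.transform(X).shape == (10, 2)


class TestPCA:
    def test_rank_one_matrix_first_component_explains_all(self, rng):
        t = rng.normal(size=12)
        p = np.array([1.0, 2.0, -1.0])
        X = np.outer(t, p)
        with pytest.warns(UserWarning):
            model = chem.NipalsPCA(n_components=2).fit(X)
        assert model.explained_variance_ratio_[0] == pytest.approx(1.0, abs=1e-10)

    def test_matches_svd_oracle(self, rng):
        X = rng.normal(size=(6, 4))
        model = chem.NipalsPCA(n_components=3).fit(X)
        Xc = X - X.mean(axis=0)
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        for a in range(3):
            v = Vt[a]
            sign = np.sign(v[np.argmax(np.abs(v))])
            np.testing.assert_allclose(model.loadings_[:, a], sign * v, atol=1e-8)
            np.testing.assert_allclose(model.scores_[:, a], sign * U[:, a] * s[a],
                                       atol=1e-8)

    def test_identical_rows_truncate_to_no_components(self):
        X = np.tile([1.0, 2.0, 3.0], (5, 1))
        with pytest.warns(UserWarning, match="rank"):
            model = chem.NipalsPCA(n_components=2).fit(X)
        assert model.n_components_ == 0
        assert model.scores_.shape == (5, 0)

    def test_loadings_orthonormal_and_scores_consistent(self, rng):
        X = rng.normal(size=(15, 8))
        model = chem.NipalsPCA(n_components=4).fit(X)
        G = model.loadings_.T @ model.loadings_
        np.testing.assert_allclose(G, np.eye(4), atol=1e-8)
        np.testing.assert_allclose(
            model.scores_, (X - X.mean(0)) @ model.loadings_, atol=1e-8
        )


class TestPLS:
    def test_single_predictor_limit(self, rng):
        X = rng.normal(size=(20, 5)) * 0.01
        y = rng.normal(size=20)
        X[:, 2] = y
        model = chem.PLSDA(n_components=1).fit(X, y)
        w = model.x_weights_[:, 0]
        assert abs(w[2]) >= 0.99 * np.linalg.norm(w)

    def test_score_orthogonality(self, rng):
        X = rng.normal(size=(24, 50))
        Y = np.repeat(np.eye(3), 8, axis=0)
        model = chem.PLSDA(n_components=2).fit(X, Y)
        t1, t2 = model.x_scores_.T
        assert abs(t1 @ t2) <= 1e-8 * np.linalg.norm(t1) * np.linalg.norm(t2)

    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
    def test_three_group_separation_on_synthetic_default(self, seed):
        """Two PLS-DA components separate three shifted groups (positive
        silhouette), emulating scores-plot group separation."""
        from sklearn.metrics import silhouette_score

        rng = np.random.default_rng(seed)
        shifts = np.array([[0.0] * 50, [1.0] * 25 + [0.0] * 25, [0.0] * 25 + [1.0] * 25])
        labels = np.repeat([0, 1, 2], 8)
        X = rng.normal(size=(24, 50)) + shifts[labels]
        Y = np.eye(3)[labels]
        model = chem.PLSDA(n_components=2).fit(X, Y)
        assert silhouette_score(model.x_scores_, labels) > 0

    def test_first_component_matches_sklearn_pls(self, rng):
        from sklearn.cross_decomposition import PLSRegression

        X = rng.normal(size=(16, 12))
        y = np.repeat([1.0, -1.0], 8)
        mine = chem.PLSDA(n_components=2).fit(X, y)
        ref = PLSRegression(n_components=2, scale=False).fit(X, y)
        for a in range(2):
            c = np.corrcoef(mine.x_scores_[:, a], ref.x_scores_[:, a])[0, 1]
            assert abs(c) == pytest.approx(1.0, abs=1e-6)

    def test_constant_y_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            chem.PLSDA().fit(rng.normal(size=(8, 3)), np.ones(8))


class TestOPLS:
    def test_reduces_to_pls_without_orthogonal_variation(self, rng):
        y = np.repeat([1.0, -1.0], 5)
        X = np.outer(y, rng.normal(size=7))  # only class-correlated structure
        opls = chem.OPLSDA(n_orth=0, compute_q2=False).fit(X, y)
        pls = chem.PLSDA(n_components=1).fit(X, y)
        np.testing.assert_allclose(opls.t_pred_, pls.x_scores_[:, 0], atol=1e-8)

    def test_orthogonal_filter_restores_class_correlation(self):
        rng = np.random.default_rng(0)
        y = np.repeat([1.0, -1.0], 4)
        v = rng.normal(size=8)
        v -= v @ y * y / (y @ y)  # orthogonal to y
        X = np.column_stack([y + 0.3 * v, v])
        model = chem.OPLSDA(n_orth=1, compute_q2=False).fit(X, y)
        r = np.corrcoef(model.t_pred_, y)[0, 1]
        assert abs(r) >= 0.999

    def test_decomposition_identity_and_orthogonality(self, serum_smfy):
        model, X = serum_smfy["model"], serum_smfy["X"]
        recon = np.outer(model.t_pred_, model.p_pred_)
        for a in range(model.n_orth_):
            recon += np.outer(model.T_orth_[:, a], model.P_orth_[:, a])
        residual = X - recon
        t = model.t_pred_
        assert np.max(np.abs(residual.T @ t)) <= 1e-8 * (t @ t)
        for a in range(model.n_orth_):
            t_o = model.T_orth_[:, a]
            assert abs(t @ t_o) <= 1e-8 * np.linalg.norm(t) * np.linalg.norm(t_o)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError, match="single class"):
            chem.OPLSDA().fit(rng.normal(size=(6, 3)), np.ones(6))

    def test_non_pm1_coding_rejected(self, rng):
        with pytest.raises(ValueError, match="-1"):
            chem.OPLSDA().fit(rng.normal(size=(6, 3)), np.arange(6, dtype=float))


class TestCrossValidation:
    def test_fold_sizes_16_samples_7_folds(self):
        y = np.repeat([1.0, -1.0], 8)
        fold = chem.stratified_folds(y, 7, seed=0)
        sizes = sorted(np.bincount(fold, minlength=7), reverse=True)
        assert sizes == [3, 3, 2, 2, 2, 2, 2]
        # stratification: every fold's training set keeps both classes
        for f in range(7):
            assert len(np.unique(y[fold != f])) == 2

    def test_perfect_predictor_q2(self, rng):
        y = np.repeat([1.0, -1.0], 8)
        X = np.column_stack([y, rng.normal(size=(16, 5)) * 0.01])
        rep = chem.cross_validate(X, y, folds=7, seed=0)
        assert rep.q2 >= 0.99

    def test_null_labels_median_q2_nonpositive(self, rng):
        X = rng.normal(size=(16, 40))
        q2s = []
        for seed in range(50):
            y = np.repeat([1.0, -1.0], 8)
            np.random.default_rng(seed).shuffle(y)
            q2s.append(chem.cross_validate(X, y, folds=7, seed=seed).q2)
        assert np.median(q2s) <= 0

    def test_too_few_folds_rejected(self, rng):
        y = np.repeat([1.0, -1.0], 4)
        with pytest.raises(ValueError, match="folds"):
            chem.stratified_folds(y, 1)


class TestPermutationTest:
    def test_strong_signal_minimum_p(self, serum_smfy):
        X, y = serum_smfy["X"], serum_smfy["y"]
        model = chem.OPLSDA(n_orth=serum_smfy["model"].n_orth_, random_state=1)
        rep = chem.permutation_test(X, y, n_perm=200, seed=1, model=model)
        assert rep.p_perm == pytest.approx(1.0 / 201.0)
        assert len(rep.permutation_q2) == 200

    def test_observed_labels_never_among_permutations(self):
        rng = np.random.default_rng(0)
        y = np.repeat([1.0, -1.0], 3)
        for _ in range(500):
            y_p = chem.draw_label_permutation(rng, y)
            assert not np.array_equal(y_p, y)
            assert sorted(y_p) == sorted(y)

    def test_few_permutations_warn(self, rng):
        y = np.repeat([1.0, -1.0], 4)
        X = rng.normal(size=(8, 4))
        with pytest.warns(UserWarning, match="permutations"):
            chem.permutation_test(X, y, n_perm=10, seed=0, folds=4)


class TestDerivedQuantities:
    def test_vip_all_equal_weights(self):
        class Fake:
            w_pred_ = np.ones(7)

        np.testing.assert_allclose(chem.vip(Fake()), np.ones(7))

    def test_vip_hand_formula_two_variables(self):
        class Fake:
            w_pred_ = np.array([0.8, 0.6])

        np.testing.assert_allclose(
            chem.vip(Fake()), [np.sqrt(2) * 0.8, np.sqrt(2) * 0.6]
        )

    def test_vip_normalization_on_fitted_model(self, serum_smfy):
        v = serum_smfy["model"].vip_
        assert np.sum(v**2) == pytest.approx(len(v), abs=1e-6)

    def test_correlation_loadings_bounds_and_cases(self, rng):
        X = rng.normal(size=(10, 4))
        y = np.repeat([1.0, -1.0], 5)
        model = chem.OPLSDA(n_orth=0, compute_q2=False).fit(X, y)
        X2 = np.column_stack([X, model.t_pred_, np.full(10, 3.0)])
        r = chem.correlation_loadings(model, X2)
        assert np.all(np.abs(r) <= 1.0)
        assert r[4] == pytest.approx(1.0)
        assert r[5] == 0.0

    def test_loading_plot_data(self, serum_smfy):
        model, scaler = serum_smfy["model"], serum_smfy["scaler"]
        edges = serum_smfy["bm"].edges[scaler.kept_columns_]
        table = chem.loading_plot_data(model, edges, scaler)
        assert len(table) == len(edges)
        assert table["abs_r"].between(0, 1).all()

    def test_backscaled_loading_sign_for_upregulated_marker(self, serum_smfy):
        """Lactate is planted up in SMFY (coded +1): its methyl-doublet
        bucket loading must be positive."""
        model, scaler = serum_smfy["model"], serum_smfy["scaler"]
        edges = serum_smfy["bm"].edges[scaler.kept_columns_]
        table = chem.loading_plot_data(model, edges, scaler)
        sign_ref = np.sign(np.corrcoef(model.t_pred_, serum_smfy["y"])[0, 1])
        bucket = (table["ppm"] >= 1.328) & (table["ppm"] < 1.344)
        assert np.all(sign_ref * table.loc[bucket, "loading"] > 0)
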