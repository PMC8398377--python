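"""PCA and OPLS-DA: fit, equivalences, validation statistics, VIP."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import radmetab as rm
from conftest import two_class_data


class TestPca:
    def test_rank_one_data_explained_by_first_component(self):
        rng = np.random.default_rng(0)
        t = rng.normal(size=12)
        X = np.outer(t, rng.normal(size=6))
        model = rm.fit_pca(X, 2, scaling="center_only")
        assert model.explained_variance_fraction[0] == pytest.approx(1.0)

    def test_duplicated_samples_have_identical_scores(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(8, 5))
        X2 = np.vstack([X, X[:1]])
        model = rm.fit_pca(X2, 2)
        assert np.allclose(model.scores.iloc[0], model.scores.iloc[-1])

    def test_full_rank_fractions_sum_to_one(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(10, 4))
        model = rm.fit_pca(X, 4)
        assert model.explained_variance_fraction.sum() == pytest.approx(1.0)
        assert (np.diff(model.explained_variance_fraction) <= 1e-12).all()

    def test_loadings_orthonormal_and_reconstruction(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(9, 5))
        model = rm.fit_pca(X, 5)
        L = model.loadings.to_numpy()
        assert np.allclose(L.T @ L, np.eye(5), atol=1e-10)
        Xs = (X - model.mean) / model.scale
        recon = model.scores.to_numpy() @ L.T
        assert np.abs(recon - Xs).max() < 1e-8

    def test_constant_metabolite_named_in_error(self):
        X = pd.DataFrame(np.random.default_rng(4).normal(size=(6, 3)),
                         columns=["a", "b", "c"])
        X["b"] = 1.0
        with pytest.raises(ValueError, match="b"):
            rm.fit_pca(X, 2)

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(10, 6))
        m1, m2 = rm.fit_pca(X, 3), rm.fit_pca(X, 3)
        assert np.array_equal(m1.scores.to_numpy(), m2.scores.to_numpy())
        L = m1.loadings.to_numpy()
        for k in range(3):
            assert L[np.argmax(np.abs(L[:, k])), k] > 0


class TestOplsDaFit:
    def test_zero_orthogonal_equals_pls1(self):
        from sklearn.cross_decomposition import PLSRegression
        rng = np.random.default_rng(10)
        for _ in range(100):
            X, y = two_class_data(rng, n_per_class=rng.integers(4, 10),
                                  n_features=rng.integers(5, 25))
            model = rm.fit_oplsda(X, y, 0)
            pls = PLSRegression(n_components=1, scale=True)
            pls.fit(X.to_numpy(), (y == "b").astype(float))
            ref = pls.predict(X.to_numpy()).ravel()
            ours = rm.predict_oplsda(model, X).to_numpy()
            assert np.abs(ours - ref).max() <= 1e-8

    def test_orthogonal_scores_uncorrelated_with_class(self):
        rng = np.random.default_rng(11)
        for k in (1, 2, 3):
            X, y = two_class_data(rng, n_per_class=10, n_features=30)
            model = rm.fit_oplsda(X, y, k)
            yc = (y == "b").astype(float) - 0.5
            assert np.abs(model.t_orth.T @ yc).max() <= 1e-8

    def test_separable_classes_identified(self):
        rng = np.random.default_rng(12)
        # autoscaling absorbs between-class variance into the column scale
        # (a shift of s sd caps one column's class correlation at s²/(s²+4)),
        # so clear separation needs the shift spread over several metabolites
        X, y = two_class_data(rng, n_per_class=12, n_features=15,
                              shift=6.0, shift_cols=5)
        model = rm.fit_oplsda(X, y, 0)
        assert model.r2y > 0.9
        assert np.argmax(np.abs(model.w_pred)) < 5
        single = np.abs(model.w_pred)[:5].min()
        assert single > np.abs(model.w_pred)[5:].max()

    def test_orthogonal_components_never_decrease_r2y(self):
        rng = np.random.default_rng(13)
        X, y = two_class_data(rng, n_per_class=8, n_features=12)
        r2 = [rm.fit_oplsda(X, y, k).r2y for k in range(3)]
        assert r2[1] >= r2[0] - 1e-10 and r2[2] >= r2[1] - 1e-10

    def test_single_class_and_excess_rank_rejected(self):
        rng = np.random.default_rng(14)
        X = pd.DataFrame(rng.normal(size=(8, 5)))
        with pytest.raises(ValueError):
            rm.fit_oplsda(X, np.array(["a"] * 8), 0)
        y = np.array(["a"] * 4 + ["b"] * 4)
        with pytest.raises(ValueError):
            rm.fit_oplsda(X, y, 10)

    def test_vip_closed_forms(self):
        rng = np.random.default_rng(15)
        X, y = two_class_data(rng, n_per_class=8, n_features=20)
        model = rm.fit_oplsda(X, y, 1)
        vip = rm.vip_scores(model)
        assert (vip ** 2).mean() == pytest.approx(1.0, abs=1e-8)
        # one dominant weight -> VIP near sqrt(M); uniform weights -> all 1
        w = np.zeros(9); w[3] = -0.7
        model.w_pred = w / np.linalg.norm(w)
        model.vip = pd.Series(np.sqrt(9) * np.abs(model.w_pred))
        assert model.vip[3] == pytest.approx(3.0) and model.vip.drop(3).max() == 0
        w = np.ones(16) / 4.0
        assert np.allclose(np.sqrt(16) * np.abs(w), 1.0)

    def test_vip_invariant_to_column_order(self):
        rng = np.random.default_rng(16)
        X, y = two_class_data(rng, n_per_class=8, n_features=10)
        vip = rm.vip_scores(rm.fit_oplsda(X, y, 1))
        perm = rng.permutation(X.shape[1])
        vip_p = rm.vip_scores(rm.fit_oplsda(X.iloc[:, perm], y, 1))
        assert np.allclose(vip_p.sort_index(), vip.sort_index())


class TestCrossValidation:
    def test_fold_count_rule(self):
        rng = np.random.default_rng(20)
        for n_small, expect in ((12, 10), (7, 5), (4, None)):
            X, y = two_class_data(rng, n_per_class=n_small, n_features=6)
            _, _, k = rm.cross_validate(X, y, 0, seed=0)
            assert k == (expect if expect else len(y))  # LOO fallback

    def test_separable_q2_high_null_q2_low(self):
        rng = np.random.default_rng(21)
        X, y = two_class_data(rng, n_per_class=10, n_features=20,
                              shift=3.0, shift_cols=5)
        q2, _, _ = rm.cross_validate(X, y, 0, seed=1)
        assert q2 > 0.5
        null_q2 = []
        for r in range(30):
            Xn, yn = two_class_data(rng, n_per_class=10, n_features=20)
            q, _, _ = rm.cross_validate(Xn, yn, 0, seed=r)
            null_q2.append(q)
        assert np.median(null_q2) <= 0.0

    def test_q2_invariant_to_sample_order(self):
        rng = np.random.default_rng(22)
        X, y = two_class_data(rng, n_per_class=8, n_features=10)
        X.index = [f"s{i:02d}" for i in range(len(X))]
        q2, _, _ = rm.cross_validate(X, y, 1, seed=3)
        perm = rng.permutation(len(X))
        q2p, _, _ = rm.cross_validate(X.iloc[perm], y[perm], 1, seed=3)
        assert q2 == pytest.approx(q2p, abs=1e-12)


class TestCvAnova:
    def test_intercept_only_predictions_give_p_one(self):
        y = np.array(["a"] * 6 + ["b"] * 6)
        baseline = pd.Series(np.full(12, 0.5))
        f, p = rm.cv_anova(baseline, y)
        assert f == 0.0 and p == 1.0

    def test_separable_classes_give_small_p(self):
        rng = np.random.default_rng(30)
        X, y = two_class_data(rng, n_per_class=10, n_features=20,
                              shift=3.0, shift_cols=5)
        _, yhat, _ = rm.cross_validate(X, y, 0, seed=1)
        f, p = rm.cv_anova(yhat, y, n_components=1)
        assert p < 0.01

    def test_null_p_not_anticonservative(self):
        rng = np.random.default_rng(31)
        ps = []
        for r in range(200):
            X, y = two_class_data(rng, n_per_class=6, n_features=10)
            _, yhat, _ = rm.cross_validate(X, y, 0, seed=r)
            ps.append(rm.cv_anova(yhat, y)[1])
        assert np.mean(np.array(ps) < 0.05) <= 0.08

    def test_perfect_predictions_flagged_degenerate(self):
        y = np.array(["a"] * 5 + ["b"] * 5)
        exact = pd.Series((y == "b").astype(float))
        f, p = rm.cv_anova(exact, y)
        assert f > 1e10 and p < 1e-10


class TestPermutationTest:
    def test_best_possible_p_with_100_permutations(self):
        rng = np.random.default_rng(40)
        X, y = two_class_data(rng, n_per_class=10, n_features=15,
                              shift=6.0, shift_cols=5)
        res = rm.permutation_test(X, y, 0, n_permutations=100, seed=2)
        assert res["p_q2"] == pytest.approx(1 / 101)
        assert res["p_r2y"] == pytest.approx(1 / 101)

    def test_identity_permutation_counts_toward_numerator(self):
        # p can never be 0: even if every permuted stat is below the observed
        # one the add-one rule keeps p >= 1/(n+1)
        rng = np.random.default_rng(41)
        X, y = two_class_data(rng, n_per_class=6, n_features=8)
        res = rm.permutation_test(X, y, 0, n_permutations=20, seed=3)
        assert res["p_q2"] >= 1 / 21

    def test_bit_reproducible_under_seed(self):
        rng = np.random.default_rng(42)
        X, y = two_class_data(rng, n_per_class=6, n_features=8)
        r1 = rm.permutation_test(X, y, 1, n_permutations=30, seed=7)
        r2 = rm.permutation_test(X, y, 1, n_permutations=30, seed=7)
        assert np.array_equal(r1["null_q2"], r2["null_q2"])
        assert r1["p_q2"] == r2["p_q2"] and r1["q2"] == r2["q2"]


class TestChooseNOrthogonal:
    def test_no_orthogonal_structure_returns_zero(self):
        rng = np.random.default_rng(50)
        n = 24
        y = np.array(["a"] * 12 + ["b"] * 12)
        signal = np.where(y == "b", 1.0, -1.0)
        X = pd.DataFrame(np.outer(signal, rng.normal(size=10))
                         + 0.3 * rng.normal(size=(n, 10)))
        assert rm.choose_n_orthogonal(X, y, k_max=3, seed=1) == 0

    def test_strong_confounder_direction_returns_at_least_one(self):
        rng = np.random.default_rng(51)
        n = 24
        y = np.array(["a"] * 12 + ["b"] * 12)
        signal = np.where(y == "b", 0.5, -0.5)
        confounder = rng.normal(size=n) * 4.0  # big y-orthogonal variation
        X = pd.DataFrame(np.outer(signal, rng.normal(size=12))
                         + np.outer(confounder, rng.normal(size=12))
                         + 0.3 * rng.normal(size=(n, 12)))
        assert rm.choose_n_orthogonal(X, y, k_max=3, seed=1) >= 1

    def test_k_max_zero(self):
        rng = np.random.default_rng(52)
        X, y = two_class_data(rng, n_per_class=6, n_features=8)
        assert rm.choose_n_orthogonal(X, y, k_max=0, seed=0) == 0


def test_validate_oplsda_bundles_statistics():
    rng = np.random.default_rng(60)
    X, y = two_class_data(rng, n_per_class=10, n_features=20,
                          shift=4.0, shift_cols=4)
    model = rm.validate_oplsda(X, y, n_orthogonal=0, n_permutations=50, seed=5)
    assert model.q2 is not None and model.q2 > 0.5
    assert model.q2 <= model.r2y
    assert model.cv_anova_p < 0.01
    assert model.permutation_p_q2 == pytest.approx(1 / 51)
    assert model.is_validated()
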