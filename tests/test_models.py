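"""Kernels, mixed-model RR/KRR, PLS and kernel PLS, component selection."""

import numpy as np
import pytest

from grainshape.models import (
    GenotypeMatrix,
    KernelMatrix,
    additive_cross,
    additive_relationship,
    fit_kpls,
    fit_krr,
    fit_pls,
    fit_rr,
    gaussian_cross,
    gaussian_kernel,
    median_heuristic_bandwidth,
    predict_kpls,
    predict_pls,
    predict_rr_krr,
    select_ncomp,
)


def random_genotypes(rng, n=30, m=50, maf=(0.1, 0.5)):
    p = rng.uniform(*maf, size=m)
    scores = np.where(rng.random((n, m)) < p, 1.0, -1.0)
    return GenotypeMatrix(scores, [f"a{i}" for i in range(n)], [f"m{j}" for j in range(m)])


class TestAdditiveRelationship:
    def test_identical_rows_share_relationship(self):
        # accessions a and b are genotypically identical (c keeps the
        # markers polymorphic so the normalizer is defined)
        scores = np.array(
            [[1.0, -1.0, 1.0, 1.0], [1.0, -1.0, 1.0, 1.0], [-1.0, 1.0, -1.0, 1.0]]
        )
        K = additive_relationship(GenotypeMatrix(scores, ["a", "b", "c"], list("wxyz")))
        v = K.values
        assert v[0, 1] == pytest.approx(v[0, 0]) == pytest.approx(v[1, 1])

    def test_matches_brute_force_formula(self):
        rng = np.random.default_rng(1)
        G = random_genotypes(rng, n=4, m=6)
        K = additive_relationship(G).values
        # independent direct evaluation: center by column means, divide
        # by the summed column variances 4 p (1 - p)
        X = G.scores
        W = X - X.mean(axis=0)
        p = (X.mean(axis=0) + 1.0) / 2.0
        expected = W @ W.T / np.sum(4.0 * p * (1.0 - p))
        assert np.allclose(K, expected, atol=1e-12)

    def test_duplicated_marker_only_rescales(self):
        rng = np.random.default_rng(2)
        G = random_genotypes(rng, n=8, m=10)
        K1 = additive_relationship(G).values
        dup = np.hstack([G.scores, G.scores[:, :1]])
        G2 = GenotypeMatrix(dup, G.accession_ids, G.marker_ids + ["dup"])
        K2 = additive_relationship(G2).values
        # recompute oracle with the duplicated column
        X = dup
        W = X - X.mean(axis=0)
        p = (X.mean(axis=0) + 1.0) / 2.0
        assert np.allclose(K2, W @ W.T / np.sum(4 * p * (1 - p)), atol=1e-12)

    def test_marker_order_invariance(self):
        rng = np.random.default_rng(3)
        G = random_genotypes(rng, n=10, m=20)
        perm = rng.permutation(20)
        G2 = GenotypeMatrix(G.scores[:, perm], G.accession_ids,
                            [G.marker_ids[j] for j in perm])
        assert np.allclose(additive_relationship(G).values,
                           additive_relationship(G2).values, atol=1e-12)

    def test_monomorphic_markers_rejected(self):
        scores = np.ones((3, 4))
        scores[:, :] = 1.0
        G = GenotypeMatrix(scores, ["a", "b", "c"], list("wxyz"))
        with pytest.raises(ValueError, match="monomorphic"):
            additive_relationship(G)


class TestGaussianKernel:
    def test_identical_rows_give_unit_entry(self):
        rows = np.array([[1.0, -1.0], [1.0, -1.0], [-1.0, 1.0]])
        K = gaussian_kernel(rows, h=0.3).values
        assert K[0, 1] == pytest.approx(1.0)
        assert np.all(np.diag(K) == 1.0)

    def test_entry_matches_definition(self):
        rows = np.array([[0.0, 0.0], [3.0, 4.0]])  # distance 5
        K = gaussian_kernel(rows, h=0.1).values
        assert K[0, 1] == pytest.approx(np.exp(-0.1 * 25.0))

    def test_median_heuristic_matches_double_loop(self, rng):
        rows = rng.normal(size=(5, 7))
        h = median_heuristic_bandwidth(rows)
        ds = [np.linalg.norm(rows[i] - rows[j])
              for i in range(5) for j in range(i + 1, 5)]
        assert h == pytest.approx(2.0 / np.median(ds) ** 2)

    def test_entries_in_unit_interval(self, rng):
        K = gaussian_kernel(rng.normal(size=(12, 6))).values
        assert np.all(K > 0) and np.all(K <= 1.0)

    def test_identical_accessions_break_median_heuristic(self):
        rows = np.ones((4, 3))
        with pytest.raises(ValueError, match="identical"):
            gaussian_kernel(rows)


class TestMixedModel:
    def test_constant_response_predicts_constant(self, rng):
        G = random_genotypes(rng, n=20, m=30)
        K = additive_relationship(G)
        model = fit_rr(K, np.full(20, 2.5))
        pred = predict_rr_krr(model, K.values[:4])
        assert np.allclose(pred, 2.5)

    def test_zero_kernel_rows_predict_intercept(self, rng):
        G = random_genotypes(rng, n=15, m=30)
        K = additive_relationship(G)
        y = rng.normal(size=15)
        model = fit_rr(K, y)
        pred = predict_rr_krr(model, np.zeros((2, 15)))
        assert np.allclose(pred, model.mu)

    def test_prediction_formula_matches_dense_solve(self, rng):
        G = random_genotypes(rng, n=10, m=25)
        K = additive_relationship(G)
        y = rng.normal(size=10)
        model = fit_rr(K, y)
        lam = model.lambda_[0]
        expected = model.mu + K.values[:3] @ np.linalg.solve(
            K.values + lam * np.eye(10), y - model.mu
        )
        assert np.allclose(predict_rr_krr(model, K.values[:3]).ravel(), expected.ravel(), atol=1e-8)

    def test_loo_recovers_kernel_signal(self, rng):
        G = random_genotypes(rng, n=50, m=80)
        K = additive_relationship(G).values
        alpha = rng.normal(size=50)
        y = K @ alpha + 0.05 * rng.normal(size=50)
        preds = np.zeros(50)
        for i in range(50):
            tr = np.delete(np.arange(50), i)
            Ktr = KernelMatrix(K[np.ix_(tr, tr)], kind="additive-relationship")
            model = fit_rr(Ktr, y[tr])
            preds[i] = predict_rr_krr(model, K[i, tr]).ravel()[0]
        assert np.corrcoef(preds, y)[0, 1] > 0.8

    def test_krr_mirrors_rr_with_gaussian_kernel(self, rng):
        G = random_genotypes(rng, n=40, m=60)
        K = gaussian_kernel(G.scores)
        alpha = rng.normal(size=40)
        y = K.values @ alpha + 0.05 * rng.normal(size=40)
        model = fit_krr(K, y)
        pred = predict_rr_krr(model, K.values)
        assert np.corrcoef(pred.ravel(), y)[0, 1] > 0.9
        with pytest.raises(ValueError):
            fit_krr(additive_relationship(G), y)

    def test_variance_ratio_recovery(self, rng):
        # y = mu + g + e with sigma_g^2 / sigma_e^2 = 4 -> lambda = 0.25;
        # 500 response replicates share one kernel (vectorized REML)
        n, reps = 200, 500
        G = random_genotypes(rng, n=n, m=300)
        K = additive_relationship(G)
        s, U = np.linalg.eigh(K.values)
        s = np.maximum(s, 0.0)
        L = U * np.sqrt(s)
        g = L @ rng.normal(size=(n, reps)) * 2.0  # sigma_g = 2
        Y = 1.0 + g + rng.normal(size=(n, reps))  # sigma_e = 1
        model = fit_rr(K, Y)
        assert 0.15 <= np.median(model.lambda_) <= 0.40

    def test_location_equivariance(self, rng):
        G = random_genotypes(rng, n=25, m=40)
        K = additive_relationship(G)
        y = rng.normal(size=25)
        p0 = predict_rr_krr(fit_rr(K, y), K.values[:5])
        p1 = predict_rr_krr(fit_rr(K, y + 10.0), K.values[:5])
        assert np.allclose(p1 - p0, 10.0, atol=1e-6)

    def test_dimension_mismatch_rejected(self, rng):
        G = random_genotypes(rng, n=10, m=20)
        model = fit_rr(additive_relationship(G), rng.normal(size=10))
        with pytest.raises(ValueError, match="columns"):
            predict_rr_krr(model, np.zeros((2, 7)))


class TestPLS:
    def test_saturated_fit_reproduces_y(self, rng):
        X = rng.normal(size=(9, 9)) + 3 * np.eye(9)
        Y = rng.normal(size=(9, 4))
        model = fit_pls(X, Y, 8)
        assert np.allclose(predict_pls(model, X), Y, atol=1e-6)

    def test_first_weight_proportional_to_xty(self, rng):
        X = rng.normal(size=(20, 10))
        y = rng.normal(size=20)
        model = fit_pls(X, y, 1)
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        direction = Xc.T @ yc
        cos = model.W[:, 0] @ direction / np.linalg.norm(direction)
        assert abs(abs(cos) - 1.0) < 1e-10

    def test_matches_sklearn_nipals_reference(self, rng):
        from sklearn.cross_decomposition import PLSRegression

        X = rng.normal(size=(12, 8))
        Y = rng.normal(size=(12, 3))
        Xt = rng.normal(size=(4, 8))
        for nc in (1, 2, 4):
            mine = predict_pls(fit_pls(X, Y, nc), Xt)
            ref = (
                PLSRegression(n_components=nc, scale=False, tol=1e-12, max_iter=5000)
                .fit(X, Y)
                .predict(Xt)
            )
            assert np.allclose(mine, ref, atol=1e-6)

    def test_excessive_rank_rejected(self, rng):
        X = rng.normal(size=(6, 3))
        Y = rng.normal(size=(6, 2))
        with pytest.raises(ValueError, match="rank"):
            fit_pls(X, Y, 5)
        with pytest.raises(ValueError):
            fit_pls(X, Y, 0)


class TestKPLS:
    @pytest.mark.parametrize("seed", range(5))
    def test_linear_kernel_equals_pls(self, seed):
        rng = np.random.default_rng(seed)
        n, m, q = rng.integers(8, 20), rng.integers(3, 12), rng.integers(1, 6)
        X = rng.normal(size=(n, m))
        Y = rng.normal(size=(n, q))
        Xt = rng.normal(size=(4, m))
        nc = int(min(4, n - 1, m))
        pls = fit_pls(X, Y, nc)
        kpls = fit_kpls(X @ X.T, Y, nc)
        assert np.allclose(
            predict_pls(pls, Xt), predict_kpls(kpls, Xt @ X.T), atol=1e-6
        )

    def test_constant_y_predicts_constant(self, rng):
        X = rng.normal(size=(10, 5))
        Y = np.full((10, 3), 1.5)
        model = fit_kpls(X @ X.T, Y, 2)
        assert model.ncomp == 0
        assert np.allclose(predict_kpls(model, X[:2] @ X.T), 1.5)

    def test_saturated_training_fit(self, rng):
        X = rng.normal(size=(8, 12))
        Y = rng.normal(size=(8, 3))
        model = fit_kpls(X @ X.T, Y, 7)
        assert np.allclose(predict_kpls(model, X @ X.T), Y, atol=1e-6)


class TestSelectNcomp:
    def test_max_one_returns_one(self, rng):
        X = rng.normal(size=(20, 10))
        Y = rng.normal(size=(20, 3))
        assert select_ncomp(X, Y, max_ncomp=1, seed=0) == 1

    def test_two_latent_components_recovered(self):
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(1000 + seed)
            n, m = 60, 40
            T = rng.normal(size=(n, 2))
            X = T @ rng.normal(size=(2, m)) + 0.05 * rng.normal(size=(n, m))
            Y = T @ rng.normal(size=(2, 6)) + 0.1 * rng.normal(size=(n, 6))
            if select_ncomp(X, Y, max_ncomp=10, seed=seed) in (2, 3):
                hits += 1
        assert hits >= 45  # >= 90% of replicates

    def test_pure_noise_prefers_one_component(self):
        chosen = []
        for seed in range(15):
            rng = np.random.default_rng(2000 + seed)
            X = rng.normal(size=(40, 25))
            Y = rng.normal(size=(40, 5))
            chosen.append(select_ncomp(X, Y, max_ncomp=8, seed=seed))
        values, counts = np.unique(chosen, return_counts=True)
        assert values[np.argmax(counts)] == 1

    def test_kernel_input_uses_kpls_path(self, rng):
        X = rng.normal(size=(30, 15))
        Y = rng.normal(size=(30, 4))
        K = gaussian_kernel(X)
        nc = select_ncomp(K, Y, max_ncomp=5, seed=3)
        assert 1 <= nc <= 5
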