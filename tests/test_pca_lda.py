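"""PCA and PCA-subspace LDA against brute-force oracles."""

import numpy as np
import pytest

from desimilk.lda import PCALDA, bootstrap_ccr, choose_n_pcs
from desimilk.pca import PCA, pca_q2


class TestPCA:
    def test_rank_one_noiseless_single_component(self, rng):
        X = np.outer(rng.normal(size=8), rng.normal(size=12))
        res = PCA(X).fit(1)
        assert res.explained[0] == pytest.approx(1.0, abs=1e-9)

    def test_projection_identity(self, rng):
        X = rng.normal(size=(10, 6))
        res = PCA(X).fit(3)
        np.testing.assert_allclose(res.scores, (X - X.mean(0)) @ res.loadings, atol=1e-10)

    @pytest.mark.parametrize("shape", [(6, 4), (12, 9), (20, 20)])
    def test_matches_eigendecomposition_oracle(self, shape, rng):
        X = rng.normal(size=shape)
        k = min(shape[0] - 1, shape[1])
        res = PCA(X).fit(k)
        Xc = X - X.mean(0)
        evals, evecs = np.linalg.eigh(Xc.T @ Xc)
        evals, evecs = evals[::-1], evecs[:, ::-1]
        np.testing.assert_allclose(res.explained, (evals / evals.sum())[:k], atol=1e-8)
        for j in range(k):
            # eigenvectors defined up to sign
            dot = abs(res.loadings[:, j] @ evecs[:, j])
            assert dot == pytest.approx(1.0, abs=1e-8)

    def test_matches_sklearn(self, rng):
        sk = pytest.importorskip("sklearn.decomposition")
        X = rng.normal(size=(15, 8))
        res = PCA(X).fit(4)
        ref = sk.PCA(n_components=4).fit(X)
        np.testing.assert_allclose(res.explained, ref.explained_variance_ratio_, atol=1e-8)

    def test_loadings_orthonormal_and_signs_deterministic(self, rng):
        X = rng.normal(size=(12, 7))
        a, b = PCA(X).fit(5), PCA(X).fit(5)
        np.testing.assert_allclose(a.loadings.T @ a.loadings, np.eye(5), atol=1e-8)
        np.testing.assert_allclose(a.loadings, b.loadings)
        for j in range(5):
            i = np.argmax(np.abs(a.loadings[:, j]))
            assert a.loadings[i, j] > 0

    def test_reconstruction_error_non_increasing(self, rng):
        X = rng.normal(size=(10, 8))
        res = PCA(X).fit(6)
        errs = [np.sum((X - res.reconstruct(k)) ** 2) for k in range(1, 7)]
        assert all(e2 <= e1 + 1e-12 for e1, e2 in zip(errs, errs[1:]))
        assert res.explained.sum() <= 1 + 1e-12

    def test_k_too_large_rejected(self, rng):
        with pytest.raises(ValueError):
            PCA(rng.normal(size=(5, 10))).fit(5)


class TestPCAQ2:
    def test_noiseless_rank_one_predictable(self, rng):
        X = np.outer(rng.normal(size=21), rng.normal(size=30))
        assert pca_q2(X, 1, seed=0)[0] >= 0.99

    def test_iid_noise_not_predictable(self):
        q2s = [pca_q2(np.random.default_rng(i).normal(size=(25, 40)), 1, seed=i)[0]
               for i in range(20)]
        assert np.median(q2s) <= 0

    def test_q2_below_r2x(self, rng):
        for _ in range(5):
            X = rng.normal(size=(18, 12)) + 3 * np.outer(rng.normal(size=18),
                                                         rng.normal(size=12))
            res = PCA(X).fit(3)
            assert np.all(res.q2(seed=0) <= res.r2x_cumulative + 1e-9)

    def test_too_many_folds_rejected(self, rng):
        with pytest.raises(ValueError):
            pca_q2(rng.normal(size=(5, 4)), 1, folds=6)


def _two_clouds(rng, n=20, d=8, sep=10.0):
    X = np.vstack([rng.normal(size=(n, d)), rng.normal(size=(n, d)) + sep / np.sqrt(d)])
    y = np.array(["a"] * n + ["b"] * n)
    return X, y


class TestLDA:
    def test_separated_clouds_perfect_training_ccr(self, rng):
        X, y = _two_clouds(rng)
        res = PCALDA(X, y, n_pcs=4).fit()
        pred = res.classify(X).with_truth(y)
        assert pred.ccr_including == 1.0

    def test_permuted_labels_near_chance(self, rng):
        X = rng.normal(size=(150, 10))
        y = np.array(list("abcde") * 30)
        res = PCALDA(X, y, n_pcs=4).fit()
        ccr = res.classify(X).with_truth(y).ccr_including
        assert 0.10 <= ccr <= 0.45  # 5 balanced classes, chance 0.2

    def test_centroid_classifies_to_own_class(self, rng):
        X, y = _two_clouds(rng)
        res = PCALDA(X, y, n_pcs=4).fit()
        centroid = X[y == "a"].mean(axis=0, keepdims=True)
        pred = res.classify(centroid)
        assert pred.assigned[0] == "a"
        assert pred.distance[0] < 1.0 and not pred.outlier[0]

    def test_far_point_flagged_outlier(self, rng):
        X, y = _two_clouds(rng)
        res = PCALDA(X, y, n_pcs=4, outlier_sigma=5.0).fit()
        far = X.mean(axis=0, keepdims=True) + 1e3
        assert res.classify(far).outlier[0]

    def test_mahalanobis_against_brute_force(self, rng):
        from scipy.spatial.distance import mahalanobis

        X, y = _two_clouds(rng, n=15, d=6, sep=4)
        res = PCALDA(X, y, n_pcs=4).fit()
        z = res.transform(X)
        VI = np.linalg.inv(res.pooled_cov)
        got = res.mahalanobis(X)
        for j, cls in enumerate(res.classes):
            ref = [mahalanobis(zi, res.class_means[cls], VI) for zi in z]
            np.testing.assert_allclose(got[:, j], ref, atol=1e-8)

    def test_small_class_rejected(self, rng):
        X = rng.normal(size=(5, 4))
        with pytest.raises(ValueError):
            PCALDA(X, np.array(["a", "a", "a", "a", "b"])).fit()

    def test_choose_n_pcs_rule(self):
        explained = np.array([0.6, 0.3, 0.05, 0.03, 0.02])
        assert choose_n_pcs(explained, 0.95) == 3
        assert choose_n_pcs(explained, 0.95, cap=2) == 2

    def test_axis_count_bounded_by_classes(self, rng):
        X = rng.normal(size=(30, 12))
        y = np.array(["a", "b", "c"] * 10)
        res = PCALDA(X, y, n_pcs=6).fit()
        assert res.directions.shape[1] == 2


class TestBootstrapCCR:
    def _fm(self, rng, n_samples=20, spectra_per=3, sep=8.0):
        import pandas as pd

        from desimilk.preprocess import BinGrid, FeatureMatrix
        rows, meta = [], []
        for i in range(n_samples):
            cls = "a" if i % 2 == 0 else "b"
            centre = np.zeros(10) if cls == "a" else np.full(10, sep / np.sqrt(10))
            centre = centre + rng.normal(scale=0.3, size=10)  # sample effect
            for s in range(spectra_per):
                rows.append(centre + rng.normal(scale=0.5, size=10))
                meta.append({"sample_id": f"s{i}", "species": cls, "scan": s,
                             "adulteration_fraction": 0.0, "source_id": "f"})
        grid = BinGrid(low=100, high=102, width=0.2)
        return FeatureMatrix(values=np.array(rows), grid=grid, meta=pd.DataFrame(meta))

    def test_separated_classes_reach_full_ccr(self, rng):
        fm = self._fm(rng)
        agg = bootstrap_ccr(fm, repeats=5, seed=0, n_pcs=4)
        assert agg.ccr_excluding == 1.0

    def test_deterministic_under_seed(self, rng):
        fm = self._fm(rng)
        a = bootstrap_ccr(fm, repeats=1, seed=7, n_pcs=4)
        b = bootstrap_ccr(fm, repeats=1, seed=7, n_pcs=4)
        assert (a.n_correct_excl, a.n_total_excl) == (b.n_correct_excl, b.n_total_excl)

    def test_shuffled_labels_near_chance(self, rng):
        fm = self._fm(rng, n_samples=30, sep=8.0)
        labels = rng.permutation(fm.labels)
        agg = bootstrap_ccr(fm, labels=labels, repeats=10, seed=0, n_pcs=4)
        assert 0.2 <= agg.ccr_excluding <= 0.8  # two classes, chance 0.5

    def test_ccr_ordering_when_outliers_misclassified(self):
        from desimilk.lda import ClassificationResult
        pred = ClassificationResult(
            assigned=np.array(["a", "a", "b", "b"]),
            distance=np.array([1.0, 1.0, 1.0, 9.0]),
            outlier=np.array([False, False, False, True]),
        ).with_truth(np.array(["a", "a", "b", "a"]))
        # the flagged outlier is misclassified, so excluding it can only help
        assert pred.ccr_excluding >= pred.ccr_including
        assert pred.ccr_excluding == 1.0 and pred.ccr_including == 0.75

    def test_class_too_small_to_stratify(self, rng):
        fm = self._fm(rng, n_samples=4, spectra_per=2)
        with pytest.raises(ValueError):
            bootstrap_ccr(fm, holdout_fraction=0.9, repeats=1)
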