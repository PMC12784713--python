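import numpy as np
import pytest

from methylstruct.dapc import (
    assignment_accuracy,
    axis_significance,
    fit_dapc,
    fit_pca,
)


def _two_group_data(rng, n_per=20, n_markers=10, shift=10.0):
    X = rng.normal(size=(2 * n_per, n_markers))
    X[n_per:, 0] += shift  # separation on marker 0 only
    labels = np.array(["g1"] * n_per + ["g2"] * n_per)
    return X, labels


class TestPca:
    def test_dominant_direction(self):
        rng = np.random.default_rng(0)
        t = rng.normal(size=200)
        X = np.column_stack([t, t]) + rng.normal(scale=0.01, size=(200, 2))
        X -= X.mean(axis=0)
        model = fit_pca(X, 2)
        np.testing.assert_allclose(np.abs(model.loadings[:, 0]), np.sqrt(0.5), atol=0.01)
        # sign convention: largest-magnitude loading positive
        assert model.loadings[np.argmax(np.abs(model.loadings[:, 0])), 0] > 0

    def test_eigenvalue_sum_is_total_variance(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 5))
        X -= X.mean(axis=0)
        model = fit_pca(X, 5)
        assert model.eigenvalues.sum() == pytest.approx(X.var(axis=0, ddof=1).sum())

    def test_rank_one_matrix(self):
        u = np.linspace(-1, 1, 10)[:, None]
        X = u @ np.array([[1.0, 2.0, 3.0]])
        X -= X.mean(axis=0)
        model = fit_pca(X, 2)
        assert model.eigenvalues[1] == pytest.approx(0.0, abs=1e-10)

    def test_too_many_components_rejected(self):
        with pytest.raises(ValueError):
            fit_pca(np.zeros((4, 3)), 4)

    def test_matches_sklearn(self):
        from sklearn.decomposition import PCA

        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 8))
        X -= X.mean(axis=0)
        ours = fit_pca(X, 4)
        ref = PCA(n_components=4).fit(X)
        np.testing.assert_allclose(ours.eigenvalues, ref.explained_variance_, atol=1e-8)
        for a in range(4):
            dot = abs(np.dot(ours.loadings[:, a], ref.components_[a]))
            assert dot == pytest.approx(1.0, abs=1e-8)


class TestDapc:
    def test_separable_groups(self):
        rng = np.random.default_rng(3)
        X, labels = _two_group_data(rng)
        model = fit_dapc(X, labels)
        loads = np.abs(model.marker_loadings[:, 0])
        assert np.argmax(loads) == 0
        assert loads[0] > 3 * loads[1:].max()
        assert assignment_accuracy(model, X, labels) == 1.0

    def test_loadings_reproduce_scores(self):
        rng = np.random.default_rng(4)
        X, labels = _two_group_data(rng, n_per=15, n_markers=30, shift=2.0)
        model = fit_dapc(X, labels)
        centered = X - model.pca.means
        np.testing.assert_allclose(
            centered @ model.marker_loadings, model.scores, atol=1e-6
        )

    def test_duplicating_individuals_preserves_axes(self):
        rng = np.random.default_rng(5)
        X, labels = _two_group_data(rng, shift=3.0)
        base = fit_dapc(X, labels)
        doubled = fit_dapc(np.vstack([X, X]), np.concatenate([labels, labels]))

        def unit(v):
            return v / np.linalg.norm(v, axis=0)

        np.testing.assert_allclose(
            np.abs(unit(doubled.marker_loadings)),
            np.abs(unit(base.marker_loadings)),
            atol=1e-6,
        )

    def test_singleton_group_rejected(self):
        X = np.random.default_rng(6).normal(size=(5, 4))
        with pytest.raises(ValueError, match="fewer than 2"):
            fit_dapc(X, ["a", "a", "a", "a", "b"])

    def test_single_group_rejected(self):
        X = np.random.default_rng(7).normal(size=(4, 3))
        with pytest.raises(ValueError, match="2 groups"):
            fit_dapc(X, ["a"] * 4)

    def test_predictions_match_sklearn_lda(self):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        rng = np.random.default_rng(8)
        n = 60
        X = rng.normal(size=(n, 20))
        labels = np.repeat(["a", "b", "c"], n // 3)
        X[labels == "b", :3] += 4.0
        X[labels == "c", 3:6] += 4.0
        model = fit_dapc(X, labels, n_pcs=2)
        T = (X - model.pca.means) @ model.pca.loadings
        ref = LinearDiscriminantAnalysis(priors=[1 / 3] * 3).fit(T, labels)
        np.testing.assert_array_equal(model.predict(X), ref.predict(T))

    def test_null_overfitting_below_one_and_shrinks_with_n(self):
        """Resubstitution accuracy on exchangeable data is inflated above
        chance by LDA overfitting on K-1 PCs, but stays below 1 on average
        and decreases as individuals are added."""
        means = {}
        for n_per in (10, 30):
            rng = np.random.default_rng(9)
            accs = [
                assignment_accuracy(
                    m := fit_dapc(
                        X := rng.normal(size=(2 * n_per, 50)),
                        lab := np.array(["g1", "g2"] * n_per),
                    ),
                    X,
                    lab,
                )
                for _ in range(200)
            ]
            means[n_per] = np.mean(accs)
        assert 0.5 < means[10] < 0.95
        assert means[30] < means[10]

    def test_accuracy_beats_permuted_labels(self):
        rng = np.random.default_rng(10)
        X, labels = _two_group_data(rng, n_per=15, n_markers=20, shift=3.0)
        model = fit_dapc(X, labels)
        true_acc = assignment_accuracy(model, X, labels)
        perm_accs = []
        for _ in range(100):
            perm = rng.permutation(labels)
            perm_accs.append(
                assignment_accuracy(fit_dapc(X, perm), X, perm)
            )
        assert true_acc >= np.mean(perm_accs)

    def test_marker_mismatch_rejected(self):
        rng = np.random.default_rng(11)
        X, labels = _two_group_data(rng)
        model = fit_dapc(X, labels)
        with pytest.raises(ValueError, match="marker set"):
            assignment_accuracy(model, X[:, :5], labels)


class TestAxisSignificance:
    def test_strong_axis_flagged_and_f_matches_anova_identity(self):
        rng = np.random.default_rng(12)
        n_per = 10
        X = rng.normal(scale=0.1, size=(2 * n_per, 6))
        labels = np.array(["g1"] * n_per + ["g2"] * n_per)
        X[n_per:, 0] += 10.0
        model = fit_dapc(X, labels)
        sig = axis_significance(model)
        assert sig.significant[0]
        assert sig.q_values[0] < 1e-6
        # F from the between/within decomposition, computed directly
        y = model.scores[:, 0]
        grand = y.mean()
        ssb = sum(
            (y[labels == g].mean() - grand) ** 2 * (labels == g).sum()
            for g in ("g1", "g2")
        )
        ssw = sum(((y[labels == g] - y[labels == g].mean()) ** 2).sum() for g in ("g1", "g2"))
        f_direct = (ssb / 1) / (ssw / (2 * n_per - 2))
        assert sig.f_statistic[0] == pytest.approx(f_direct)

    def test_constant_axis_degenerate(self):
        rng = np.random.default_rng(13)
        X, labels = _two_group_data(rng, n_per=8, n_markers=6, shift=5.0)
        model = fit_dapc(X, labels)
        model.scores = np.zeros_like(model.scores)
        sig = axis_significance(model)
        assert sig.degenerate[0]
        assert sig.p_values[0] == 1.0
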