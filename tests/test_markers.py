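import numpy as np
import pytest
from scipy import stats

from methylstruct.dapc import fit_dapc
from methylstruct.markers import (
    AccuracyCurve,
    MarkerRanking,
    accuracy_curve,
    default_grid,
    fit_piecewise,
    loading_mahalanobis,
    mahalanobis_ranking,
    segmented_minimal_set,
)


def _make_curve(sizes, accuracy):
    """Curve object with a dummy ranking (enough markers to index)."""
    n = int(max(sizes))
    ranking = MarkerRanking(
        markers=None,
        distances=np.arange(n, 0, -1, dtype=float),
        p_values=np.zeros(n),
        q_values=np.zeros(n),
        order=np.arange(n),
        significant=np.ones(n, dtype=bool),
        axes_used=np.array([0]),
    )
    return AccuracyCurve(
        sizes=np.asarray(sizes), accuracy=np.asarray(accuracy, float), ranking=ranking
    )


class TestLoadingMahalanobis:
    def test_mean_vector_has_zero_distance(self):
        rng = np.random.default_rng(0)
        L = rng.normal(size=(50, 3))
        L[0] = L[1:].mean(axis=0)  # row 0 then equals the overall mean too
        d2, p = loading_mahalanobis(L)
        assert d2[0] == pytest.approx(0.0, abs=1e-10)
        assert p[0] == pytest.approx(1.0)

    def test_one_axis_reduces_to_squared_zscore(self):
        rng = np.random.default_rng(1)
        z = rng.normal(size=(200, 1))
        d2, p = loading_mahalanobis(z)
        centered = z[:, 0] - z.mean()
        np.testing.assert_allclose(d2, centered**2 / centered.var(ddof=1), atol=1e-10)
        # chi2_1 upper tail equals the two-sided normal p-value
        np.testing.assert_allclose(p, 2 * stats.norm.sf(np.sqrt(d2)), atol=1e-12)

    def test_affine_invariance(self):
        rng = np.random.default_rng(2)
        L = rng.normal(size=(300, 4))
        A = rng.normal(size=(4, 4)) + 4 * np.eye(4)
        d2, _ = loading_mahalanobis(L)
        d2_t, _ = loading_mahalanobis(L @ A + rng.normal(size=4))
        np.testing.assert_allclose(d2_t, d2, rtol=1e-8)


class TestRanking:
    def test_outlier_markers_top_ranked_and_significant(self, strong_site_dataset):
        from methylstruct.io import compute_rpm
        from methylstruct.transforms import hellinger

        (data, meta, truth), _ = strong_site_dataset
        hel = hellinger(compute_rpm(data))
        model = fit_dapc(hel, meta.sites_of(data.individuals))
        ranking = mahalanobis_ranking(model)
        strong = {data.markers.index(m) for m in truth.cluster_informative}
        top = set(ranking.order[: len(strong)])
        assert len(top & strong) / len(strong) >= 0.9
        assert all(ranking.significant[j] for j in strong)

    def test_ranking_is_permutation(self, strong_site_dataset):
        from methylstruct.io import compute_rpm
        from methylstruct.transforms import hellinger

        (data, meta, _), _ = strong_site_dataset
        hel = hellinger(compute_rpm(data))
        model = fit_dapc(hel, meta.sites_of(data.individuals))
        ranking = mahalanobis_ranking(model, axes="all")
        assert sorted(ranking.order) == list(range(len(data.markers)))
        assert (ranking.distances >= 0).all()


class TestAccuracyCurve:
    def test_single_point_grid_matches_full_model(self, strong_site_dataset):
        from methylstruct.dapc import assignment_accuracy
        from methylstruct.io import compute_rpm
        from methylstruct.transforms import hellinger

        (data, meta, _), _ = strong_site_dataset
        hel = hellinger(compute_rpm(data))
        labels = meta.sites_of(data.individuals)
        model = fit_dapc(hel, labels)
        ranking = mahalanobis_ranking(model)
        n_sig = ranking.n_significant
        curve = accuracy_curve(hel, labels, ranking, grid=[n_sig])
        cols = ranking.top(n_sig)
        ref = fit_dapc(hel.values[:, cols], labels)
        assert len(curve.sizes) == 1
        assert curve.accuracy[0] == pytest.approx(
            assignment_accuracy(ref, hel.values[:, cols], labels)
        )

    def test_grid_outside_significant_rejected(self, strong_site_dataset):
        from methylstruct.io import compute_rpm
        from methylstruct.transforms import hellinger

        (data, meta, _), _ = strong_site_dataset
        hel = hellinger(compute_rpm(data))
        labels = meta.sites_of(data.individuals)
        model = fit_dapc(hel, labels)
        ranking = mahalanobis_ranking(model)
        with pytest.raises(ValueError, match="grid"):
            accuracy_curve(hel, labels, ranking, grid=[ranking.n_significant + 1])

    def test_default_grid_shape(self):
        grid = default_grid(117)
        assert grid[0] == 10 and grid[-1] == 117
        assert all(b > a for a, b in zip(grid, grid[1:]))
        assert default_grid(25) == list(range(1, 26))  # too few points: every rank


class TestSegmented:
    def test_two_segment_construction_recovered(self):
        """Noiseless rise to 0.9 at x=50 then flat: the first breakpoint of
        the AIC-best model lands within one grid step of 50."""
        sizes = np.arange(5, 201, 5)
        acc = np.where(sizes <= 50, 0.1 + 0.8 * (sizes / 50), 0.9)
        seg, _ = segmented_minimal_set(_make_curve(sizes, acc))
        assert abs(seg.first_breakpoint - 50) <= 5

    def test_three_segment_construction_recovered(self):
        sizes = np.arange(10, 301, 10)
        acc = np.piecewise(
            sizes.astype(float),
            [sizes <= 30, (sizes > 30) & (sizes <= 120), sizes > 120],
            [lambda x: 0.2 + 0.01 * x, lambda x: 0.5 + 0.002 * (x - 30), lambda x: 0.68],
        )
        seg, minimal = segmented_minimal_set(_make_curve(sizes, acc))
        bps = np.sort(seg.selected["breakpoints"])
        assert abs(bps[0] - 30) <= 10
        assert any(abs(b - 120) <= 10 for b in bps)
        assert seg.minimal_size == pytest.approx(30, abs=10)

    def test_linear_curve_flags_flat_break(self):
        sizes = np.arange(5, 101, 5)
        acc = 0.2 + 0.005 * sizes
        seg, _ = segmented_minimal_set(_make_curve(sizes, acc))
        assert seg.flat_break_warning

    def test_aic_formula(self):
        sizes = np.arange(5, 101, 5)
        acc = np.where(sizes <= 40, 0.01 * sizes, 0.4) + 0.001 * (sizes % 3)
        seg, _ = segmented_minimal_set(_make_curve(sizes, acc))
        n = len(sizes)
        for cand in seg.candidates:
            b = cand["n_breakpoints"]
            expected = n * np.log(max(cand["rss"], 1e-12) / n) + 2 * (2 + 2 * b)
            assert cand["aic"] == pytest.approx(expected)

    def test_piecewise_fit_is_continuous(self):
        rng = np.random.default_rng(3)
        x = np.linspace(0, 100, 40)
        y = rng.normal(size=40)
        psi = np.array([30.0, 60.0])
        coefs, rss, fitted = fit_piecewise(x, y, psi)
        for b in psi:
            left = np.interp(b - 1e-9, x, fitted)
            right = np.interp(b + 1e-9, x, fitted)
            assert left == pytest.approx(right, abs=1e-6)
        assert rss >= 0

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="4 curve points"):
            segmented_minimal_set(_make_curve([1, 2, 3], [0.1, 0.2, 0.3]))
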