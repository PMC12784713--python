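import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from methylstruct.indval import (
    characteristic_markers,
    indval,
    jenks_one_break,
)


def _brute_force_indval(X, labels, groups):
    """Independent per-cell evaluation of specificity x fidelity x 100."""
    X = np.asarray(X, float)
    out = np.zeros((X.shape[1], len(groups)))
    for j in range(X.shape[1]):
        means = [X[np.asarray(labels) == g, j].mean() for g in groups]
        for gi, g in enumerate(groups):
            rows = X[np.asarray(labels) == g, j]
            A = means[gi] / sum(means) if sum(means) > 0 else 0.0
            B = float(np.mean(rows > 0))
            out[j, gi] = A * B * 100.0
    return out


class TestIndval:
    def test_perfect_indicator(self):
        X = np.array([[5.0, 0], [3.0, 0], [0.0, 1], [0.0, 2]])
        table = indval(X, ["g1", "g1", "g2", "g2"])
        assert table.indval[0, 0] == pytest.approx(100.0)
        assert table.indval[0, 1] == pytest.approx(0.0)

    def test_uniform_marker_splits_evenly(self):
        X = np.ones((8, 1))
        labels = ["a", "a", "b", "b", "c", "c", "d", "d"]
        table = indval(X, labels)
        np.testing.assert_allclose(table.indval[0], 25.0)
        np.testing.assert_allclose(table.A[0], 0.25)
        np.testing.assert_allclose(table.B[0], 1.0)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        X = rng.gamma(0.5, 2.0, size=(6, 4)) * rng.integers(0, 2, size=(6, 4))
        labels = ["g1", "g1", "g1", "g2", "g2", "g2"]
        table = indval(X, labels)
        np.testing.assert_allclose(
            table.indval, _brute_force_indval(X, labels, table.groups), atol=1e-12
        )
        sums = table.A[X.mean(axis=0) > 0].sum(axis=1) if (X.mean(axis=0) > 0).any() else []
        np.testing.assert_allclose(sums, 1.0, atol=1e-12)

    def test_label_permutation_equivariance(self):
        rng = np.random.default_rng(1)
        X = rng.gamma(1, 5, size=(9, 5))
        labels = np.array(["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        base = indval(X, labels)
        swapped = indval(X, np.where(labels == "a", "b", np.where(labels == "b", "a", "c")))
        np.testing.assert_allclose(
            swapped.indval[:, [1, 0, 2]], base.indval, atol=1e-12
        )

    @given(st.floats(0.01, 100.0))
    @settings(derandomize=True, deadline=None, max_examples=30)
    def test_global_scale_invariance(self, scale):
        rng = np.random.default_rng(2)
        X = rng.gamma(1, 5, size=(6, 3))
        labels = ["g1"] * 3 + ["g2"] * 3
        base = indval(X, labels)
        scaled = indval(X * scale, labels)
        np.testing.assert_allclose(scaled.indval, base.indval, atol=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            indval(np.ones((2, 2)), ["a", "a"], groups=["a", "b"])


class TestJenks:
    @pytest.mark.parametrize(
        "values, expected_upper",
        [
            ((1, 2, 10, 11), [False, False, True, True]),
            ((0, 100), [False, True]),
            ((90, 5, 5, 5, 5), [True, False, False, False, False]),
            ((50, 48, 2, 2, 2), [True, True, False, False, False]),
        ],
    )
    def test_examples(self, values, expected_upper):
        _, upper = jenks_one_break(np.asarray(values, float))
        assert list(upper) == expected_upper

    def test_all_equal_rejected(self):
        with pytest.raises(ValueError, match="no break"):
            jenks_one_break(np.array([3.0, 3.0, 3.0]))

    @given(
        st.lists(st.integers(0, 50), min_size=2, max_size=12).filter(
            lambda v: len(set(v)) > 1
        )
    )
    @settings(derandomize=True, deadline=None, max_examples=100)
    def test_split_is_sse_optimal(self, values):
        """Exhaustive independent check: no other ordered split has a
        smaller total within-class SSE."""
        v = np.asarray(values, float)
        _, upper = jenks_one_break(v)
        s = np.sort(v)

        def sse(chunk):
            return float(((chunk - chunk.mean()) ** 2).sum()) if len(chunk) else 0.0

        chosen = sse(v[~upper]) + sse(v[upper])
        best = min(sse(s[:i]) + sse(s[i:]) for i in range(1, len(s)))
        assert chosen == pytest.approx(best, abs=1e-9)


class TestCharacteristic:
    def test_flags_follow_breaks(self):
        X = np.array(
            [
                [10.0, 0.1, 0.1],
                [9.0, 0.2, 0.1],
                [0.1, 8.0, 7.0],
                [0.2, 9.0, 8.0],
                [0.1, 0.1, 0.1],
                [0.2, 0.1, 0.2],
            ]
        )
        labels = ["a", "a", "b", "b", "c", "c"]
        table = characteristic_markers(indval(X, labels))
        assert table.characteristic[0].tolist() == [True, False, False]
        # marker 2 is high in both b-group columns of the transposed view
        counts = table.characteristic.sum(axis=0)
        assert counts[0] >= 1

    def test_uniform_marker_characteristic_of_none(self):
        X = np.ones((4, 2))
        table = characteristic_markers(indval(X, ["a", "a", "b", "b"]))
        assert not table.characteristic.any()
        assert np.isnan(table.breaks).all()

    def test_recovers_planted_exclusive_markers(self, strong_site_dataset):
        """Markers planted as elevated in one site cluster are flagged as
        characteristic of that cluster for >= 90% of the planted set."""
        from methylstruct.io import compute_rpm

        (data, meta, truth), _ = strong_site_dataset
        rpm = compute_rpm(data)
        cluster_of = {s: c for s, c in truth.site_cluster.items()}
        unit_labels = np.array([cluster_of[meta.site[i]] for i in data.individuals])
        table = characteristic_markers(indval(rpm.values, unit_labels, markers=data.markers))
        groups = list(table.groups)
        hits = 0
        for marker, cl in truth.cluster_informative.items():
            j = data.markers.index(marker)
            hits += bool(table.characteristic[j, groups.index(cl)])
        assert hits / len(truth.cluster_informative) >= 0.9
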