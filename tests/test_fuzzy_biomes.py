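"""Fuzzy c-means, fuzzy silhouette selection, ternary biome classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from stressbiomes.config import DEFAULT_TRIANGLE
from stressbiomes.fuzzy_biomes import (
    FuzzyPartition,
    detect_polytolerance,
    fuzzy_kmeans,
    fuzzy_silhouette,
    label_clusters_and_rescale,
    polytolerance_summary,
    select_k_fuzzy_silhouette,
)


def _blobs(rng, centers, n_per=50, sd=0.1):
    pts = [c + rng.normal(0, sd, (n_per, 2)) for c in np.atleast_2d(centers)]
    return np.vstack(pts)


class TestFuzzyKMeans:
    def test_equidistant_point_has_split_membership(self):
        """A point midway between two symmetric clusters gets (0.5, 0.5)."""
        rng = np.random.default_rng(0)
        X = np.vstack([
            _blobs(rng, [[-1.0, 0.0]], 30, 0.01),
            _blobs(rng, [[1.0, 0.0]], 30, 0.01),
            [[0.0, 0.0]],
        ])
        part = fuzzy_kmeans(X, K=2, seed=1)
        np.testing.assert_allclose(part.U[-1], [0.5, 0.5], atol=0.01)

    def test_point_on_centroid_gets_full_membership(self):
        X = np.array([[0.0, 0.0], [0.0, 0.0], [0.0, 0.0], [5.0, 5.0], [5.0, 5.0]])
        part = fuzzy_kmeans(X, K=2, seed=0)
        # the first three points coincide with their centroid exactly
        assert part.U[0].max() == pytest.approx(1.0)
        assert part.U[0].min() == pytest.approx(0.0)

    def test_matches_multistart_brute_force_on_toy(self):
        """On a 12-point 2-cluster toy, the objective and hard assignment
        match a 200-restart brute-force search keeping the best J."""
        rng = np.random.default_rng(3)
        X = np.vstack([
            _blobs(rng, [[0.0, 0.0]], 6, 0.2), _blobs(rng, [[4.0, 4.0]], 6, 0.2)
        ])
        part = fuzzy_kmeans(X, K=2, seed=0, tol=1e-10)
        best = min(
            (fuzzy_kmeans(X, K=2, seed=s, tol=1e-10) for s in range(200)),
            key=lambda p: p.objective,
        )
        assert part.objective == pytest.approx(best.objective, rel=1e-6)
        assert adjusted_rand_score(part.hard_labels(), best.hard_labels()) == 1.0

    def test_objective_monotone_in_debug_mode(self, rng):
        X = rng.normal(size=(100, 2))
        part = fuzzy_kmeans(X, K=3, seed=5, debug=True)  # raises if J rises
        assert part.objective >= 0

    def test_memberships_rows_sum_to_one(self, rng):
        X = rng.normal(size=(80, 2))
        part = fuzzy_kmeans(X, K=4, seed=2)
        np.testing.assert_allclose(part.U.sum(axis=1), 1.0, atol=1e-9)
        assert part.U.min() >= 0 and part.U.max() <= 1

    def test_crisp_limit_matches_kmeans(self):
        """As m -> 1+, hard assignments equal crisp k-means run from the
        same initialization on well-separated data."""
        rng = np.random.default_rng(9)
        X = _blobs(rng, [[0, 0], [5, 5], [0, 5]], 40, 0.3)
        n = len(X)
        init_rng = np.random.default_rng(11)
        init = X[init_rng.choice(n, 3, replace=False)]
        part = fuzzy_kmeans(X, K=3, m=1.05, seed=11)
        km = KMeans(n_clusters=3, init=init, n_init=1).fit(X)
        assert adjusted_rand_score(part.hard_labels(), km.labels_) == 1.0

    def test_parameter_validation(self, rng):
        X = rng.normal(size=(10, 2))
        with pytest.raises(ValueError):
            fuzzy_kmeans(X, K=10)
        with pytest.raises(ValueError):
            fuzzy_kmeans(X, K=2, m=1.0)


class TestSelectK:
    def test_two_planted_gaussians_give_k2(self):
        rng = np.random.default_rng(1)
        X = _blobs(rng, [[0, 0], [5, 5]], 100, 0.3)
        best_k, scores, _ = select_k_fuzzy_silhouette(X, (2, 3, 4, 5), n_rep=20, seed=1)
        assert best_k == 2

    def test_four_planted_groups_give_k4(self):
        """Vertex + center structure, as in the tolerance triangle."""
        rng = np.random.default_rng(2)
        centers = np.array([[1, -0.5], [0, 1], [-1, -0.5], [0, 0]])
        X = _blobs(rng, centers, 150, 0.1)
        best_k, scores, _ = select_k_fuzzy_silhouette(
            X, (2, 3, 4, 5, 6), n_rep=30, seed=2
        )
        assert best_k == 4

    def test_perfect_partition_has_high_fs(self):
        rng = np.random.default_rng(4)
        X = _blobs(rng, [[0, 0], [100, 100]], 30, 0.01)
        part = fuzzy_kmeans(X, K=2, seed=0)
        assert fuzzy_silhouette(X, part) > 0.9

    def test_degenerate_partition_rejected(self):
        part = FuzzyPartition(
            U=np.ones((10, 2)) * [1.0, 0.0], centroids=np.zeros((2, 2)),
            m=2.0, objective=0.0, iterations=1, converged=True,
        )
        with pytest.raises(ValueError, match="degenerate"):
            fuzzy_silhouette(np.random.default_rng(0).normal(size=(10, 2)), part)


def _partition_from_U(U, centroids):
    return FuzzyPartition(
        U=np.asarray(U, dtype=float), centroids=np.asarray(centroids, dtype=float),
        m=2.0, objective=0.0, iterations=1, converged=True,
    )


class TestTernary:
    #: centroids near drought, shade, waterlogging/cold vertices + center
    CENTROIDS = [[0.9, -0.45], [0.05, 0.9], [-0.9, -0.4], [0.02, 0.05]]

    def test_row_rescaling_arithmetic(self):
        U = np.array([[0.1, 0.2, 0.3, 0.4]])
        part = _partition_from_U(U, self.CENTROIDS)
        tern, labels = label_clusters_and_rescale(part, DEFAULT_TRIANGLE)
        np.testing.assert_allclose(
            tern[["t_drought", "t_shade", "t_waterlogging_cold"]].iloc[0],
            [1 / 6, 1 / 3, 1 / 2],
        )
        assert labels[3] == "low_intermediate"

    def test_dominant_membership_keeps_biome(self):
        U = np.array([[0.97, 0.01, 0.01, 0.01]])
        part = _partition_from_U(U, self.CENTROIDS)
        tern, _ = label_clusters_and_rescale(part, DEFAULT_TRIANGLE)
        row = tern.iloc[0]
        assert row["stb"] == "drought"
        assert row["t_drought"] == pytest.approx(0.97 / 0.99, abs=1e-9)

    def test_centroid_on_each_vertex_gets_that_label(self):
        verts = list(DEFAULT_TRIANGLE.values())
        centroids = verts + [[0.0, 0.0]]
        U = np.full((2, 4), 0.25)
        part = _partition_from_U(U, centroids)
        _, labels = label_clusters_and_rescale(part, DEFAULT_TRIANGLE)
        for i, name in enumerate(DEFAULT_TRIANGLE):
            assert labels[i] == name

    def test_ambiguous_labelling_raises(self):
        # two centroids hug the drought vertex; shade vertex claims one of
        # them only if it is nearest, here both claim the same centroid
        centroids = [[0.9, -0.45], [0.95, -0.5], [0.0, 0.0], [-0.1, 0.1]]
        part = _partition_from_U(np.full((3, 4), 0.25), centroids)
        with pytest.raises(ValueError, match="ambiguous"):
            label_clusters_and_rescale(part, DEFAULT_TRIANGLE)

    def test_wrong_k_rejected(self):
        part = fuzzy_kmeans(np.random.default_rng(0).normal(size=(30, 2)), K=3, seed=0)
        with pytest.raises(ValueError, match="K=4"):
            label_clusters_and_rescale(part, DEFAULT_TRIANGLE)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0.01, 1.0), min_size=4, max_size=4))
    def test_ternary_rows_always_sum_to_one(self, raw):
        U = np.array([raw]) / np.sum(raw)
        part = _partition_from_U(U, self.CENTROIDS)
        tern, _ = label_clusters_and_rescale(part, DEFAULT_TRIANGLE)
        total = tern[["t_drought", "t_shade", "t_waterlogging_cold"]].iloc[0].sum()
        assert total == pytest.approx(1.0, abs=1e-9)


class TestPolytolerance:
    @staticmethod
    def _tern(rows):
        return pd.DataFrame(
            rows, columns=["t_drought", "t_shade", "t_waterlogging_cold"]
        )

    @pytest.mark.parametrize(
        "row,expected",
        [
            ((0.5, 0.5, 0.0), "shade_drought"),
            ((0.0, 0.5, 0.5), "shade_wc"),
            ((0.5, 0.0, 0.5), "excluded_pair"),
            ((0.7, 0.2, 0.1), "none"),
            ((0.4, 0.6, 0.0), "shade_drought"),  # inclusive endpoints
            ((0.39, 0.61, 0.0), "none"),
            ((1 / 3, 1 / 3, 1 / 3), "none"),  # below the band
        ],
    )
    def test_band_rule(self, row, expected):
        assert detect_polytolerance(self._tern([row])).iloc[0] == expected

    def test_classes_are_single_valued_partition_subset(self, rng):
        raw = rng.dirichlet([1, 1, 1], size=500)
        tern = self._tern(raw)
        classes = detect_polytolerance(tern)
        assert set(classes.unique()) <= {
            "none", "shade_drought", "shade_wc", "excluded_pair"
        }
        # every row in the band rule really satisfies it
        for i, cls in classes.items():
            top2 = np.sort(raw[i])[-2:]
            in_band = np.all((top2 >= 0.4) & (top2 <= 0.6))
            assert (cls != "none") == in_band

    def test_band_validation(self):
        with pytest.raises(ValueError):
            detect_polytolerance(self._tern([(0.5, 0.5, 0.0)]), 0.7, 0.6)

    def test_summary_counts_and_percentages(self):
        tern = self._tern([(0.5, 0.5, 0.0)] * 2 + [(0.8, 0.1, 0.1)] * 8)
        summary = polytolerance_summary(detect_polytolerance(tern))
        sd = summary.set_index("class")
        assert sd.loc["shade_drought", "n"] == 2
        assert sd.loc["shade_drought", "pct"] == pytest.approx(20.0)
        assert sd.loc["shade_wc", "n"] == 0
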