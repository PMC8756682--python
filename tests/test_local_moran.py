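"""Local Moran (LISA), conditional permutation and cluster classification."""

import numpy as np
import pytest

from spatialepi import (classify_clusters, cluster_counts,
                        conditional_permutation, from_adjacency_pairs,
                        global_moran, global_moran_bivariate, lisa,
                        local_moran, local_moran_bivariate, make_grid_frame,
                        queen_adjacency, row_standardize,
                        shared_border_adjacency)
from spatialepi.errors import FormatError


def naive_local_moran(weights, x):
    """Per-unit loop evaluation of the printed LISA formula."""
    dense = weights.matrix.toarray()
    n = len(x)
    z = x - x.mean()
    den = float(z @ z)
    return np.array([n * z[i] / den * sum(dense[i, j] * z[j]
                                          for j in range(n))
                     for i in range(n)])


class TestLocalMoran:
    def test_matches_naive_loop(self, rng):
        for _ in range(10):
            rows, cols = rng.integers(2, 8, size=2)
            weights = row_standardize(queen_adjacency(
                make_grid_frame(rows, cols)))
            x = rng.normal(size=rows * cols)
            got = local_moran(weights, x).local_i
            assert np.max(np.abs(got - naive_local_moran(weights, x))) < 1e-12

    def test_sum_equals_s0_times_global(self, queen_8x8_std, rng):
        x = rng.normal(size=64)
        stats = local_moran(queen_8x8_std, x)
        global_i = global_moran(queen_8x8_std, x).statistic
        assert abs(stats.local_i.sum()
                   - queen_8x8_std.s0 * global_i) < 1e-10

    def test_center_spike_signs_on_3x3_rook(self, grid_3x3):
        weights = row_standardize(shared_border_adjacency(grid_3x3))
        x = np.zeros(9)
        x[4] = 1.0  # r1c1 center
        stats = local_moran(weights, x)
        assert stats.quadrant[4] == "HL"  # high value, low neighbors
        for idx in (1, 3, 5, 7):          # rook neighbors of the center
            assert stats.quadrant[idx] == "LH"

    def test_island_convention(self):
        weights = from_adjacency_pairs(["A", "B", "C"], [("A", "B")])
        stats = local_moran(weights, np.array([1.0, 2.0, 3.0]))
        assert stats.local_i[2] == 0.0
        assert stats.cluster_label[2] == "island"
        assert stats.quadrant[2] is None


class TestBivariateLocal:
    def test_reduction_quadrants_match_univariate(self, queen_8x8_std, rng):
        x = rng.normal(size=64)
        uni = local_moran(queen_8x8_std, x)
        biv = local_moran_bivariate(queen_8x8_std, x, x)
        assert biv.quadrant == uni.quadrant
        np.testing.assert_allclose(biv.local_i, uni.local_i, atol=1e-12)

    def test_sum_equals_s0_times_global_bivariate(self, queen_8x8_std, rng):
        x = rng.normal(size=64)
        y = rng.normal(size=64)
        stats = local_moran_bivariate(queen_8x8_std, x, y)
        global_i = global_moran_bivariate(queen_8x8_std, x, y).statistic
        assert abs(stats.local_i.sum()
                   - queen_8x8_std.s0 * global_i) < 1e-10

    def test_anticorrelated_blocks_flag_outliers(self, queen_10x10_std):
        x = np.zeros(100)
        x[:50] = 1.0
        y = 1.0 - x
        stats = lisa(queen_10x10_std, x, y, permutations=999, seed=3)
        left_labels = {stats.cluster_label[i] for i in range(30)
                       if stats.pseudo_p[i] <= 0.05}
        assert left_labels == {"high_low_outlier"}


class TestConditionalPermutation:
    def test_p_values_live_on_counting_grid_with_floor(self, queen_10x10_std):
        """Pseudo p-values are exact multiples of 1/(R + 1), never below the
        1/(R + 1) floor, and a strongly clustered pattern drives interior
        units close to it."""
        x = np.zeros(100)
        x[:50] = 1.0
        p = conditional_permutation(queen_10x10_std, x, permutations=999,
                                    seed=4)
        finite = p[np.isfinite(p)]
        counts = finite * 1000
        np.testing.assert_allclose(counts, np.round(counts), atol=1e-9)
        assert finite.min() >= 1 / 1000 - 1e-12
        assert finite.min() <= 5 / 1000  # binary data can tie a few draws
        assert finite.max() <= 1.0

    def test_deterministic_under_seed(self, queen_10x10_std, rng):
        x = rng.normal(size=100)
        a = conditional_permutation(queen_10x10_std, x, permutations=199,
                                    seed=8)
        b = conditional_permutation(queen_10x10_std, x, permutations=199,
                                    seed=8)
        np.testing.assert_array_equal(a, b)

    def test_too_few_permutations_rejected(self, queen_10x10_std, rng):
        with pytest.raises(FormatError, match=">= 19"):
            conditional_permutation(queen_10x10_std, rng.normal(size=100),
                                    permutations=5)

    def test_island_gets_nan(self):
        weights = from_adjacency_pairs(["A", "B", "C", "D"],
                                       [("A", "B"), ("B", "C")])
        p = conditional_permutation(weights, np.array([1.0, 4.0, 2.0, 3.0]),
                                    permutations=99, seed=0)
        assert np.isnan(p[3])
        assert np.all(np.isfinite(p[:3]))

    def test_false_positive_rate_calibrated(self, queen_10x10_std):
        """Average share of significant units under iid noise is near alpha."""
        rates = []
        for s in range(30):
            x = np.random.default_rng(1000 + s).normal(size=100)
            p = conditional_permutation(queen_10x10_std, x, permutations=999,
                                        seed=s)
            rates.append(np.mean(p <= 0.05))
        assert 0.02 <= np.mean(rates) <= 0.10


class TestClassification:
    def _manual_stats(self, weights, z, lag, p):
        from spatialepi.local_moran import LocalMoranStats, _quadrants
        islands = weights.island_mask
        return LocalMoranStats(
            ids=list(weights.ids), local_i=z * lag, z_value=z, lag_value=lag,
            quadrant=_quadrants(z, lag, islands), pseudo_p=p,
            cluster_label=["island" if i else "not_significant"
                           for i in islands])

    def test_significant_quadrants_become_cluster_labels(self, rook_2x2):
        z = np.array([1.2, 1.2, -0.5, -0.5])
        lag = np.array([0.8, -0.8, -0.3, 0.3])
        p = np.array([0.001, 0.2, 0.01, 0.04])
        stats = classify_clusters(self._manual_stats(rook_2x2, z, lag, p),
                                  alpha=0.05)
        assert stats.cluster_label == ["hotspot", "not_significant",
                                       "coldspot", "low_high_outlier"]
        assert stats.quadrant == ["HH", "HL", "LL", "LH"]

    def test_zero_z_tie_breaks_low(self, rook_2x2):
        z = np.array([0.0, 0.0, 1.0, -1.0])
        lag = np.array([0.5, -0.5, 0.5, -0.5])
        stats = self._manual_stats(rook_2x2, z, lag, np.full(4, 0.001))
        assert stats.quadrant[:2] == ["LH", "LL"]

    def test_invalid_alpha_rejected(self, rook_2x2):
        stats = self._manual_stats(rook_2x2, np.ones(4), np.ones(4),
                                   np.full(4, 0.01))
        with pytest.raises(FormatError, match="alpha"):
            classify_clusters(stats, alpha=1.5)

    def test_alpha_monotonicity(self, queen_10x10_std, rng):
        x = rng.normal(size=100) + np.repeat(np.arange(10), 10) * 0.3
        stats = lisa(queen_10x10_std, x, permutations=999, seed=12)
        sig_counts = []
        for alpha in (0.01, 0.05, 0.10, 0.20):
            relabelled = classify_clusters(stats, alpha)
            counts = cluster_counts(relabelled)
            sig_counts.append(counts["hotspot"] + counts["coldspot"]
                              + counts["high_low_outlier"]
                              + counts["low_high_outlier"])
        assert sig_counts == sorted(sig_counts)

    def test_labels_invariant_to_affine_rescale(self, queen_10x10_std, rng):
        x = rng.normal(size=100)
        a = lisa(queen_10x10_std, x, permutations=499, seed=6)
        b = lisa(queen_10x10_std, 3.0 * x + 10.0, permutations=499, seed=6)
        assert a.cluster_label == b.cluster_label
        assert a.quadrant == b.quadrant


class TestClusterCounts:
    def test_counts_partition_n(self, queen_10x10_std, rng):
        stats = lisa(queen_10x10_std, rng.normal(size=100),
                     permutations=99, seed=0)
        counts = cluster_counts(stats)
        assert sum(counts.values()) == 100

    def test_explicit_labels(self):
        weights = from_adjacency_pairs(["A", "B", "C", "D"],
                                       [("A", "B"), ("B", "C"), ("A", "C")])
        stats = lisa(weights, np.array([5.0, 6.0, 1.0, 2.0]),
                     permutations=99, seed=0)
        stats.cluster_label = ["hotspot", "hotspot", "coldspot", "island"]
        counts = cluster_counts(stats)
        assert counts == {"hotspot": 2, "coldspot": 1, "island": 1,
                          "high_low_outlier": 0, "low_high_outlier": 0,
                          "not_significant": 0}
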