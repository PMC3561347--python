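import warnings

import numpy as np
import pytest

from sitepart.clustering import (
    GapStatistics,
    gap_curve,
    kmeans_partition,
    reference_draw,
    select_k,
    within_dispersion,
)


class TestWithinDispersion:
    def test_points_on_centroids(self):
        X = np.array([[0.0], [0.0], [10.0], [10.0]])
        assert within_dispersion(X, [1, 1, 2, 2]) == 0.0

    def test_hand_computed(self):
        assert within_dispersion(np.array([[0.0], [2.0]]), [1, 1]) == pytest.approx(2.0)

    def test_singletons_are_zero(self):
        X = np.random.default_rng(0).normal(size=(6, 3))
        assert within_dispersion(X, np.arange(1, 7)) == 0.0

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError, match="empty cluster"):
            within_dispersion(np.zeros((3, 2)), [1, 1, 3])


class TestKmeansPartition:
    def test_recovers_planted_split(self):
        rng = np.random.default_rng(3)
        X = np.vstack(
            [rng.normal(0, 0.05, (25, 9)), rng.normal(3, 0.05, (15, 9))]
        )
        a = kmeans_partition(X, 2, n_restarts=20, seed=1)
        assert a.sizes.tolist() == [25, 15]  # labels sorted by size
        assert len(set(a.labels[:25])) == 1 and len(set(a.labels[25:])) == 1
        # recomputable within-SS
        assert a.within_ss == pytest.approx(within_dispersion(X, a.labels), rel=1e-6)

    def test_k1_equals_total_ss(self):
        X = np.random.default_rng(4).normal(size=(30, 9))
        a = kmeans_partition(X, 1, n_restarts=1, seed=0)
        assert a.within_ss == pytest.approx(((X - X.mean(axis=0)) ** 2).sum())

    def test_k_exceeding_n_rejected(self):
        with pytest.raises(ValueError):
            kmeans_partition(np.zeros((3, 2)), 4)

    def test_row_order_invariance(self):
        rng = np.random.default_rng(5)
        X = np.vstack([rng.normal(0, 0.1, (20, 5)), rng.normal(4, 0.1, (10, 5))])
        perm = rng.permutation(30)
        a = kmeans_partition(X, 2, n_restarts=10, seed=2)
        b = kmeans_partition(X[perm], 2, n_restarts=10, seed=2)
        assert np.array_equal(a.labels[perm], b.labels)

    def test_w_k_non_increasing_in_k(self):
        X = np.random.default_rng(6).normal(size=(60, 9))
        w = [kmeans_partition(X, k, n_restarts=30, seed=3).within_ss for k in range(1, 6)]
        assert all(w[i] >= w[i + 1] - 1e-9 for i in range(len(w) - 1))


class TestReferenceDraw:
    def test_shape_preserved(self):
        X = np.random.default_rng(7).normal(size=(40, 9))
        assert reference_draw(X, seed=1).shape == (40, 9)

    def test_marginals_uniform_in_singular_basis(self):
        """Draws are exactly uniform inside the bounding box expressed in
        the data's right-singular-vector basis (KS at alpha=0.01)."""
        from scipy import stats

        rng = np.random.default_rng(8)
        X = rng.uniform([-1, 0], [1, 5], size=(400, 2))
        draws = np.vstack([reference_draw(X, seed=s) for s in range(25)])
        centred = X - X.mean(axis=0)
        _, _, Vt = np.linalg.svd(centred, full_matrices=False)
        rot_data = centred @ Vt.T
        rot_draws = (draws - X.mean(axis=0)) @ Vt.T
        for j in range(2):
            lo, hi = rot_data[:, j].min(), rot_data[:, j].max()
            u = (rot_draws[:, j] - lo) / (hi - lo)
            assert u.min() >= 0 and u.max() <= 1
            assert stats.kstest(u, "uniform").pvalue > 0.01

    def test_column_means_approach_box_midpoints(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(200, 3)) * [1.0, 2.0, 0.5]
        draws = np.vstack([reference_draw(X, seed=s) for s in range(50)])
        centred = X - X.mean(axis=0)
        _, _, Vt = np.linalg.svd(centred, full_matrices=False)
        rot = centred @ Vt.T
        mid = (rot.min(axis=0) + rot.max(axis=0)) / 2 @ Vt + X.mean(axis=0)
        half_range = (rot.max(axis=0) - rot.min(axis=0)).max() / 2
        assert np.linalg.norm(draws.mean(axis=0) - mid) < 0.05 * half_range * np.sqrt(3)

    def test_degenerate_data_rejected(self):
        with pytest.raises(ValueError):
            reference_draw(np.ones((5, 3)), seed=0)


class TestGapCurve:
    def test_planted_two_clusters_selected(self):
        rng = np.random.default_rng(10)
        X = np.vstack([rng.normal(0, 0.3, (60, 9)), rng.normal(2.5, 0.3, (60, 9))])
        hits = 0
        for seed in range(5):
            stats_ = gap_curve(X, k_max=4, B=20, n_restarts=50, seed=seed)
            k, warn = select_k(stats_)
            hits += (k == 2 and not warn)
        assert hits >= 4

    def test_b1_degenerate_run_is_finite(self):
        X = np.random.default_rng(11).normal(size=(30, 4))
        stats_ = gap_curve(X, k_max=3, B=1, n_restarts=10, seed=0)
        assert np.all(np.isfinite(stats_.gap))
        assert np.all(stats_.s_k >= 0)

    def test_sk_includes_monte_carlo_inflation(self):
        X = np.random.default_rng(12).normal(size=(40, 3))
        stats_ = gap_curve(X, k_max=3, B=10, n_restarts=10, seed=1)
        # s_k = sd * sqrt(1 + 1/B) >= sd > 0 for noisy references
        assert np.all(stats_.s_k > 0)


class TestSelectK:
    def test_published_gap_triple_selects_three(self):
        """The printed mammal gap curve: k=2 fails the rule, k=3 passes."""
        stats_ = GapStatistics(
            k_values=np.array([2, 3, 4]),
            gap=np.array([0.5980, 0.6371, 0.6209]),
            s_k=np.array([0.0087, 0.0073, 0.0066]),
            B=100,
            log_W_observed=np.zeros(3),
            mean_log_W_reference=np.zeros(3),
        )
        k, warn = select_k(stats_)
        assert k == 3 and not warn

    def test_monotone_decreasing_gap_selects_smallest_k(self):
        stats_ = GapStatistics(
            k_values=np.array([1, 2, 3]),
            gap=np.array([1.0, 0.8, 0.6]),
            s_k=np.array([0.01, 0.01, 0.01]),
            B=10,
            log_W_observed=np.zeros(3),
            mean_log_W_reference=np.zeros(3),
        )
        assert select_k(stats_) == (1, False)

    def test_no_k_satisfying_rule_returns_kmax_with_warning(self):
        stats_ = GapStatistics(
            k_values=np.array([1, 2, 3]),
            gap=np.array([0.1, 0.5, 0.9]),
            s_k=np.array([0.001, 0.001, 0.001]),
            B=10,
            log_W_observed=np.zeros(3),
            mean_log_W_reference=np.zeros(3),
        )
        assert select_k(stats_) == (3, True)

    def test_large_s_everywhere_selects_first_k(self):
        stats_ = GapStatistics(
            k_values=np.array([1, 2, 3]),
            gap=np.array([0.1, 0.5, 0.9]),
            s_k=np.array([1.0, 1.0, 1.0]),
            B=10,
            log_W_observed=np.zeros(3),
            mean_log_W_reference=np.zeros(3),
        )
        assert select_k(stats_) == (1, False)


def test_single_class_fixture_flags_no_structure():
    from sitepart.clustering import cluster_sites
    from sitepart.simulate import FixtureSpec, make_fixture

    fx = make_fixture(FixtureSpec(n_taxa=10, group_sizes=(150,), seed=6))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = cluster_sites(fx.alignment, k_max=3, B=15, n_restarts=50, seed=6)
    # either the rule stops at k=1 (no structure) or nothing satisfies it
    assert res.no_structure or res.k == 1
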