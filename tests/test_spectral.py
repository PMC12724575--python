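"""Spectral clustering core, elbow selection, boundary extraction, cohort means."""

import numpy as np
import pytest

import velozones as vz
from velozones.spectral import ClusteringError, ClusterSolution, elbow_point
from velozones.traversal import AffinityMatrix, BinGrid


def chain_beta(n=100, beta=0.1):
    C = np.zeros((n, n))
    off = np.arange(n - 1)
    C[off, off + 1] = beta
    C[off + 1, off] = beta
    return C


def block_affinity(split_points, n=100, strength=1.0, beta=0.1):
    """Banded within-block affinity plus the beta chain."""
    W = chain_beta(n, beta)
    edges = [0, *split_points, n]
    for a, b in zip(edges[:-1], edges[1:]):
        for band in (1, 2):
            idx = np.arange(a, max(a, b - band))
            W[idx, idx + band] += strength
            W[idx + band, idx] += strength
    return AffinityMatrix(W, beta=beta)


def brute_force_ncut_split(W):
    """Minimum 2-way normalised cut over all contiguous split points."""
    d = W.sum(axis=1)
    best_s, best = None, np.inf
    for s in range(1, len(W)):
        cut = W[:s, s:].sum()
        nc = cut * (1.0 / d[:s].sum() + 1.0 / d[s:].sum())
        if nc < best:
            best, best_s = nc, s
    return best_s


class TestSpectralCluster:
    def test_two_blocks_split_at_fifty(self):
        A = block_affinity([50])
        sol = vz.spectral_cluster(A, 2, seed=1, occupancy=np.ones(100))
        assert sol.contiguous
        assert np.array_equal(sol.labels, np.repeat([0, 1], 50))

    def test_matches_brute_force_ncut(self):
        """Spectral k=2 equals exhaustive minimum normalised cut over all 99
        contiguous splits, for 20 randomised two-block configurations."""
        rng = np.random.default_rng(2024)
        for _ in range(20):
            b = int(rng.integers(30, 71))
            W = chain_beta()
            for a, c in [(0, b), (b, 100)]:
                for band in (1, 2, 3):
                    idx = np.arange(a, c - band)
                    vals = rng.integers(5, 51, size=len(idx)) / 50.0
                    W[idx, idx + band] += vals
                    W[idx + band, idx] += vals
            A = AffinityMatrix(W, beta=0.1)
            sol = vz.spectral_cluster(A, 2, seed=1, occupancy=np.ones(100))
            split = int(np.flatnonzero(np.diff(sol.labels))[0] + 1)
            assert split == brute_force_ncut_split(W) == b

    def test_uniform_four_blocks_recover_analytic_wcss(self):
        """Four identical dense blocks, uniform occupancy: clusters are the
        blocks and WCSS is the closed-form sum of within-block variances."""
        n = 100
        W = chain_beta(n)
        for a in range(0, n, 25):
            W[a:a + 25, a:a + 25] += 1.0
        A = AffinityMatrix(W, beta=0.1)
        sol = vz.spectral_cluster(A, 4, seed=1, occupancy=np.ones(n))
        assert np.array_equal(np.flatnonzero(np.diff(sol.labels)) + 1, [25, 50, 75])
        centers = BinGrid().centers
        analytic = sum(
            float(((centers[a:a + 25] - centers[a:a + 25].mean()) ** 2).sum())
            for a in range(0, n, 25)
        )
        assert sol.wcss == pytest.approx(analytic)

    def test_k_bounds_enforced(self):
        A = block_affinity([50])
        with pytest.raises(ClusteringError):
            vz.spectral_cluster(A, 1, seed=1)
        with pytest.raises(ClusteringError):
            vz.spectral_cluster(A, 21, seed=1)

    def test_deterministic_given_seed(self, trace4):
        A = vz.affinity_from_traversals(vz.traversal_matrix(trace4))
        s1 = vz.spectral_cluster(A, 4, seed=7)
        s2 = vz.spectral_cluster(A, 4, seed=7)
        assert np.array_equal(s1.labels, s2.labels)
        assert s1.wcss == s2.wcss

    def test_labels_ordered_and_contiguous_on_real_traces(self, trace4):
        A = vz.affinity_from_traversals(vz.traversal_matrix(trace4))
        for k in (2, 3, 4, 5, 6):
            sol = vz.spectral_cluster(A, k, seed=3)
            assert sol.contiguous
            assert np.all(np.diff(sol.labels) >= 0)
            assert set(sol.labels) == set(range(k))

    def test_wcss_nonincreasing_in_k(self, trace4):
        A = vz.affinity_from_traversals(vz.traversal_matrix(trace4))
        wcss = [vz.spectral_cluster(A, k, seed=3).wcss for k in range(2, 11)]
        rises = np.maximum(np.diff(wcss), 0)
        assert np.all(rises <= 1e-2 * wcss[0])  # k-means local-optima tolerance


class TestElbow:
    def test_forced_curve(self):
        """WCSS collapsing by 10x between k=3 and k=4 and flat afterwards
        puts the inflection at k=4."""
        assert elbow_point(np.arange(2, 9), [100.0, 80.0, 8.0, 7.0, 6.5, 6.2, 6.0]) == 4

    def test_relative_curvature_not_absolute_drop(self):
        """The selected k follows the proportional flattening of the curve,
        not the largest absolute WCSS drop (which sits at small k for any
        steeply decaying curve)."""
        assert elbow_point(np.arange(1, 7), [100.0, 40.0, 12.0, 10.0, 9.0, 8.5]) == 3

    def test_linear_decline_tie_breaks_small(self):
        ks = np.arange(2, 8)
        assert elbow_point(ks, np.linspace(60.0, 10.0, 6)) == 3

    def test_endpoints_never_selected(self):
        ks = np.arange(2, 7)
        w = [100.0, 5.0, 4.0, 3.5, 3.2]  # sharpest bend at the left endpoint
        assert elbow_point(ks, w) in ks[1:-1]

    def test_k_range_preconditions(self):
        A = block_affinity([50])
        with pytest.raises(ClusteringError):
            vz.elbow_select(A, 1, 10, seed=1)
        with pytest.raises(ClusteringError):
            vz.elbow_select(A, 3, 4, seed=1)

    def test_recovers_generative_state_count(self, cohort4):
        """Pooled traversals from twenty 4-state traces: the elbow lands on 4."""
        pooled = vz.pool_traversals([vz.traversal_matrix(t) for t in cohort4])
        curve = vz.elbow_select(vz.affinity_from_traversals(pooled), 2, 10, seed=1)
        assert curve.k_star == 4


class TestBoundaries:
    def test_edge_arithmetic(self):
        labels = np.array([0] * 20 + [1] * 30 + [2] * 50)
        sol = ClusterSolution(k=3, labels=labels, wcss=0.0, contiguous=True)
        assert np.allclose(vz.extract_boundaries(sol), [2.0, 5.0])

    def test_single_split(self):
        labels = np.array([0] * 21 + [1] * 79)
        sol = ClusterSolution(k=2, labels=labels, wcss=0.0, contiguous=True)
        assert np.allclose(vz.extract_boundaries(sol), [2.1])

    def test_degenerate_single_cluster(self):
        sol = ClusterSolution(k=1, labels=np.zeros(100, dtype=int), wcss=0.0, contiguous=True)
        assert len(vz.extract_boundaries(sol)) == 0

    def test_non_contiguous_rejected(self):
        labels = np.array([0, 1] * 50)
        sol = ClusterSolution(k=2, labels=labels, wcss=0.0, contiguous=False)
        with pytest.raises(ClusteringError):
            vz.extract_boundaries(sol)


class TestCohortThresholds:
    def test_single_trace_mean_is_identity(self, trace4):
        zt = vz.derive_cohort_thresholds([trace4], k=4, seed=1)
        assert np.allclose(zt.boundaries, zt.per_match_boundaries[0])

    def test_duplicate_traces_mean_unchanged(self, trace4):
        one = vz.derive_cohort_thresholds([trace4], k=4, seed=1)
        two = vz.derive_cohort_thresholds([trace4, trace4], k=4, seed=1)
        assert np.allclose(one.boundaries, two.boundaries)

    def test_thresholds_strictly_increasing_and_partition(self, cohort4):
        zt = vz.derive_cohort_thresholds(cohort4[:5], k="auto", seed=1)
        b = zt.boundaries
        assert np.all(np.diff(b) > 0) and 0 < b[0] and b[-1] < 10

    def test_boundary_recovery_near_density_minima(self, cohort4):
        """Cohort-mean boundaries fall within 0.3 m/s of the occupancy-density
        minima between adjacent generative states (midpoints for equal SDs)."""
        zt = vz.derive_cohort_thresholds(cohort4, k="auto", seed=1)
        assert zt.k == 4
        assert np.all(np.abs(zt.boundaries - np.array([2.0, 4.25, 6.75])) <= 0.3)

    def test_json_round_trip(self, trace4, tmp_path):
        import json

        zt = vz.derive_cohort_thresholds([trace4], k=4, seed=1)
        p = tmp_path / "thr.json"
        zt.to_json(p)
        doc = json.loads(p.read_text())
        assert doc["k"] == 4 and len(doc["boundaries"]) == 3
        assert doc["per_match_boundaries"]
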