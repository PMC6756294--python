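import itertools

import numpy as np
import pytest

from dseg.cluster import (
    DsegModel,
    assign_segments,
    build_pq_histogram,
    canonical_segment_order,
    kmedians_fit,
    weighted_median,
)
from dseg.pq import PQVolume

from conftest import make_histogram_from_points


# ---------------------------------------------------------------- oracles
def oracle_weighted_median(values, weights):
    """Independent lower weighted median by explicit accumulation."""
    pairs = sorted(zip(values, weights))
    half = sum(w for _, w in pairs) / 2.0
    acc = 0.0
    for v, w in pairs:
        acc += w
        if acc >= half:
            return v
    return pairs[-1][0]


def oracle_partition_cost(points, weights, assignment):
    cost = 0.0
    for c in set(assignment):
        idx = [i for i, a in enumerate(assignment) if a == c]
        med = np.array(
            [
                oracle_weighted_median(points[idx, 0], weights[idx]),
                oracle_weighted_median(points[idx, 1], weights[idx]),
            ]
        )
        cost += float(np.sum(weights[idx] * np.linalg.norm(points[idx] - med, axis=1)))
    return cost


def brute_force_min_cost(points, weights, k):
    """Exhaustive search over every assignment of points to <=k clusters."""
    best = np.inf
    best_assign = None
    for assignment in itertools.product(range(k), repeat=len(points)):
        cost = oracle_partition_cost(points, weights, assignment)
        if cost < best - 1e-15:
            best = cost
            best_assign = assignment
    return best, best_assign


def pq_volume_from_points(points):
    pts = np.asarray(points, float)
    shape = (len(pts), 1, 1)
    return PQVolume(
        p=pts[:, 0].reshape(shape), q=pts[:, 1].reshape(shape), mask=np.ones(shape, bool)
    )


# ---------------------------------------------------------------- histogram
class TestHistogram:
    def test_single_value_occupies_one_bin(self):
        pts = np.full((50, 2), [1.0e-3, 0.5e-3])
        hist = build_pq_histogram([pts], n_bins=(32, 32), p_range=(0, 2e-3), q_range=(0, 1e-3))
        assert hist.n_total == 50
        assert (hist.counts > 0).sum() == 1
        assert hist.counts.max() == 50

    def test_two_scans_conserve_counts(self, rng):
        a = rng.uniform(0, 1e-3, (100, 2))
        b = rng.uniform(0, 1e-3, (100, 2))
        hist = build_pq_histogram([a, b], n_bins=(16, 16))
        assert hist.n_total == 200
        assert hist.counts.sum() == 200

    def test_uniform_counts_match_multinomial_expectation(self, rng):
        n = 200_000
        pts = rng.uniform(0.0, 1.0, (n, 2))
        hist = build_pq_histogram([pts], n_bins=(8, 8), p_range=(0, 1), q_range=(0, 1))
        expected = n / 64
        sigma = np.sqrt(n * (1 / 64) * (1 - 1 / 64))
        assert np.all(np.abs(hist.counts - expected) < 4 * sigma)

    def test_empty_masks_raise(self):
        empty = PQVolume(p=np.zeros((2, 2, 2)), q=np.zeros((2, 2, 2)), mask=np.zeros((2, 2, 2), bool))
        with pytest.raises(ValueError, match="no voxels pooled"):
            build_pq_histogram([empty])

    def test_outliers_clipped_into_end_bins_and_counted(self):
        pts = np.array([[0.5, 0.5], [10.0, 10.0]])
        hist = build_pq_histogram([pts], n_bins=(4, 4), p_range=(0, 1), q_range=(0, 1))
        assert hist.n_total == 2
        assert hist.n_clipped == 1
        assert hist.counts[-1, -1] == 1


# ---------------------------------------------------------------- k-medians
class TestWeightedMedian:
    def test_matches_oracle_on_random_inputs(self, rng):
        for _ in range(100):
            n = rng.integers(1, 12)
            v = rng.normal(size=n)
            w = rng.integers(1, 10, size=n).astype(float)
            assert weighted_median(v, w) == oracle_weighted_median(v, w)


class TestKMedians:
    def test_single_bin_k1(self):
        hist = make_histogram_from_points([[2.0, 3.0]], [7])
        model = kmedians_fit(hist, k=1)
        pts, _ = hist.nonzero_bin_centers()
        assert np.allclose(model.centroids[0], pts[0])
        assert model.objective == pytest.approx(0.0, abs=1e-12)

    def test_six_weighted_points_k2_matches_brute_force(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            pts_in = r.uniform(0, 10, (6, 2))
            cnt = r.integers(1, 9, 6)
            hist = make_histogram_from_points(pts_in, cnt, n_bins=(40, 40))
            points, weights = hist.nonzero_bin_centers()
            model = kmedians_fit(hist, k=2)
            best, _ = brute_force_min_cost(points, weights, 2)
            assert model.objective == pytest.approx(best, rel=1e-9, abs=1e-12)

    def test_k_larger_than_nonzero_bins_raises(self):
        hist = make_histogram_from_points([[0, 0], [1, 1]], [3, 3])
        with pytest.raises(ValueError, match="degenerate histogram"):
            kmedians_fit(hist, k=3)

    def test_objective_trace_is_non_increasing(self, rng):
        pts = np.vstack(
            [rng.normal(loc, 0.3, (400, 2)) for loc in ([1, 1], [4, 1], [2, 5], [6, 6])]
        )
        hist = build_pq_histogram([pts], n_bins=(48, 48))
        model = kmedians_fit(hist, k=4)
        trace = np.array(model.objective_trace)
        assert np.all(np.diff(trace) <= 1e-9 * trace[0])

    def test_determinism(self, rng):
        pts = rng.uniform(0, 1, (5000, 2))
        hist = build_pq_histogram([pts], n_bins=(64, 64))
        m1 = kmedians_fit(hist, k=16)
        m2 = kmedians_fit(hist, k=16)
        assert np.array_equal(m1.centroids, m2.centroids)
        assert m1.objective == m2.objective

    def test_random_init_is_seed_deterministic(self, rng):
        pts = rng.uniform(0, 1, (5000, 2))
        hist = build_pq_histogram([pts], n_bins=(64, 64))
        m1 = kmedians_fit(hist, k=6, init="random", seed=11)
        m2 = kmedians_fit(hist, k=6, init="random", seed=11)
        assert np.array_equal(m1.centroids, m2.centroids)

    def test_sixteen_segments_all_nonempty_on_four_tissue_mixture(self, rng):
        # four well-separated tissue blobs still fill all 16 segments
        centers = [(1.4e-3, 1.1e-3), (1.9e-3, 0.3e-3), (5.2e-3, 0.1e-3), (2.2e-3, 0.5e-3)]
        pts = np.vstack(
            [np.abs(rng.normal(c, 0.15e-3, (20000, 2))) for c in centers]
        )
        hist = build_pq_histogram([pts], n_bins=(128, 128))
        model = kmedians_fit(hist, k=16)
        vol = pq_volume_from_points(pts)
        labels = assign_segments(vol, model)
        occupied = np.unique(labels.labels[labels.mask])
        assert len(occupied) == 16


# ---------------------------------------------------------------- assignment
class TestAssign:
    def _model(self, centroids):
        c = np.asarray(centroids, float)
        order = canonical_segment_order(c)
        return DsegModel(
            centroids=c[order], canonical_order=order, objective=0.0, n_iterations=1
        )

    def test_voxel_at_centroid(self):
        model = self._model([[0.0, 0.0], [1.0, 1.0]])
        labels = assign_segments(pq_volume_from_points([[1.0, 1.0]]), model)
        assert labels.labels[labels.mask][0] == 2

    def test_equidistant_tie_goes_to_lower_canonical_index(self):
        model = self._model([[0.0, 0.0], [2.0, 0.0]])
        labels = assign_segments(pq_volume_from_points([[1.0, 0.0]]), model)
        assert labels.labels[labels.mask][0] == 1

    def test_matches_exhaustive_nearest_centroid_scan(self, rng):
        centroids = rng.uniform(0, 1, (16, 2))
        model = self._model(centroids)
        pts = rng.uniform(0, 1, (500, 2))
        labels = assign_segments(pq_volume_from_points(pts), model)
        got = labels.labels[labels.mask]
        for i, pt in enumerate(pts):
            d = np.linalg.norm(model.centroids - pt, axis=1)
            assert got[i] == int(np.argmin(d)) + 1

    def test_outside_mask_is_zero(self, rng):
        model = self._model(rng.uniform(0, 1, (4, 2)))
        p = rng.uniform(0, 1, (3, 3, 3))
        q = rng.uniform(0, 1, (3, 3, 3))
        mask = np.zeros((3, 3, 3), bool)
        mask[0] = True
        labels = assign_segments(PQVolume(p=p, q=q, mask=mask), model)
        assert np.all(labels.labels[~mask] == 0)
        assert np.all(labels.labels[mask] >= 1)


# ---------------------------------------------------------------- ordering
class TestCanonicalOrder:
    def test_sorted_centroids_identity(self):
        c = np.array([[0.0, 1.0], [1.0, 0.5], [2.0, 0.1]])
        assert np.array_equal(canonical_segment_order(c), [0, 1, 2])

    def test_equal_p_ranks_higher_q_first(self):
        c = np.array([[1.0, 0.2], [1.0, 0.9]])
        assert np.array_equal(canonical_segment_order(c), [1, 0])

    def test_idempotent(self, rng):
        c = rng.uniform(0, 1, (16, 2))
        order = canonical_segment_order(c)
        sorted_c = c[order]
        assert np.array_equal(canonical_segment_order(sorted_c), np.arange(16))


class TestModelSerialization:
    def test_json_roundtrip(self, rng, tmp_path):
        pts = rng.uniform(0, 1, (2000, 2))
        hist = build_pq_histogram([pts], n_bins=(32, 32))
        model = kmedians_fit(hist, k=5)
        path = tmp_path / "model.json"
        model.to_json(path)
        back = DsegModel.from_json(path)
        assert np.allclose(back.centroids, model.centroids)
        assert back.objective == pytest.approx(model.objective)
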