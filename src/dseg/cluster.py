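"""k-medians segmentation of the pooled (p, q) plane.

All scans are pooled into a single 2-D histogram and the histogram is
clustered once; per-scan voxels are then assigned to the shared model.
Clustering operates on count-weighted bin centres: assignment uses the
Euclidean distance (a Voronoi partition of the plane), the centroid update
is the count-weighted coordinate-wise median, and the reported objective is
the count-weighted sum of Euclidean point-to-centroid distances.

The update step minimises the L1 cost, so in rare configurations it could
raise the Euclidean objective; when that happens the previous centroids are
kept and the fit stops, which makes the objective trace non-increasing by
construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.spatial.distance import cdist

from dseg.pq import PQVolume

__all__ = [
    "PQHistogram",
    "DsegModel",
    "SegmentLabelVolume",
    "build_pq_histogram",
    "weighted_median",
    "kmedians_fit",
    "assign_segments",
    "canonical_segment_order",
]

DEFAULT_K = 16
DEFAULT_BINS = (256, 256)
RANGE_PERCENTILE = 99.9


@dataclass
class PQHistogram:
    """2-D histogram of pooled in-mask (p, q) values."""

    bin_edges_p: np.ndarray
    bin_edges_q: np.ndarray
    counts: np.ndarray  # (n_bins_p, n_bins_q) int64
    n_total: int
    n_clipped: int = 0

    def __post_init__(self) -> None:
        self.bin_edges_p = np.asarray(self.bin_edges_p, dtype=float)
        self.bin_edges_q = np.asarray(self.bin_edges_q, dtype=float)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if np.any(np.diff(self.bin_edges_p) <= 0) or np.any(np.diff(self.bin_edges_q) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if self.counts.shape != (len(self.bin_edges_p) - 1, len(self.bin_edges_q) - 1):
            raise ValueError("counts shape inconsistent with bin edges")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if int(self.counts.sum()) != self.n_total:
            raise ValueError("sum(counts) must equal n_total")

    def nonzero_bin_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Centres (n, 2) and counts (n,) of the occupied bins."""
        cp = 0.5 * (self.bin_edges_p[:-1] + self.bin_edges_p[1:])
        cq = 0.5 * (self.bin_edges_q[:-1] + self.bin_edges_q[1:])
        ip, iq = np.nonzero(self.counts)
        points = np.column_stack([cp[ip], cq[iq]])
        return points, self.counts[ip, iq].astype(float)


@dataclass
class DsegModel:
    """Fitted segment centroids in canonical order plus fit provenance.

    ``centroids[i]`` is the (p, q) centroid of canonical segment ``i + 1``.
    ``canonical_order`` records the permutation that mapped raw fit order to
    canonical order (ascending p, ties broken by descending q).
    """

    centroids: np.ndarray  # (k, 2)
    canonical_order: np.ndarray  # permutation of 0..k-1, fit order -> canonical
    objective: float
    n_iterations: int
    seed_policy: dict = field(default_factory=dict)
    objective_trace: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        self.canonical_order = np.asarray(self.canonical_order, dtype=int)
        k = self.centroids.shape[0]
        if self.centroids.shape != (k, 2):
            raise ValueError("centroids must have shape (k, 2)")
        if sorted(self.canonical_order.tolist()) != list(range(k)):
            raise ValueError("canonical_order must be a permutation of 0..k-1")
        if len(np.unique(self.centroids, axis=0)) != k:
            raise ValueError("centroids must be distinct")

    @property
    def k(self) -> int:
        return self.centroids.shape[0]

    def to_json(self, path) -> None:
        payload = {
            "centroids": self.centroids.tolist(),
            "canonical_order": self.canonical_order.tolist(),
            "objective": self.objective,
            "n_iterations": self.n_iterations,
            "seed_policy": self.seed_policy,
            "objective_trace": list(self.objective_trace),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "DsegModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            centroids=np.asarray(payload["centroids"], dtype=float),
            canonical_order=np.asarray(payload["canonical_order"], dtype=int),
            objective=payload["objective"],
            n_iterations=payload["n_iterations"],
            seed_policy=payload.get("seed_policy", {}),
            objective_trace=payload.get("objective_trace", []),
        )


@dataclass
class SegmentLabelVolume:
    """Per-voxel canonical segment labels: 0 outside the mask, 1..k inside."""

    labels: np.ndarray
    mask: np.ndarray
    model_id: str = ""
    k: int = DEFAULT_K

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int32)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.labels.shape != self.mask.shape:
            raise ValueError("labels and mask must share a shape")
        if np.any(self.labels[~self.mask] != 0):
            raise ValueError("labels must be 0 outside the mask")
        inside = self.labels[self.mask]
        if inside.size and (inside.min() < 1 or inside.max() > self.k):
            raise ValueError("in-mask labels must lie in 1..k")


def build_pq_histogram(
    pq_scans,
    n_bins: tuple[int, int] = DEFAULT_BINS,
    p_range: tuple[float, float] | None = None,
    q_range: tuple[float, float] | None = None,
) -> PQHistogram:
    """Pool in-mask (p, q) values from all scans into one 2-D histogram.

    The grid spans [0, P99.9] of each pooled axis unless explicit ranges are
    given; values beyond the range are clipped into the end bins and their
    count recorded.
    """
    scans = list(pq_scans)
    if not scans:
        raise ValueError("no scans supplied")
    points = [s.masked_points() if isinstance(s, PQVolume) else np.asarray(s, float) for s in scans]
    pooled = np.concatenate([pt for pt in points if pt.size], axis=0) if any(
        pt.size for pt in points
    ) else np.empty((0, 2))
    if pooled.shape[0] == 0:
        raise ValueError("no voxels pooled: all masks are empty")

    if p_range is None:
        hi = float(np.percentile(pooled[:, 0], RANGE_PERCENTILE))
        p_range = (0.0, hi if hi > 0 else float(pooled[:, 0].max()) or 1.0)
    if q_range is None:
        hi = float(np.percentile(pooled[:, 1], RANGE_PERCENTILE))
        q_range = (0.0, hi if hi > 0 else max(float(pooled[:, 1].max()), 1e-12))

    n_clipped = int(
        np.sum(
            (pooled[:, 0] < p_range[0])
            | (pooled[:, 0] > p_range[1])
            | (pooled[:, 1] < q_range[0])
            | (pooled[:, 1] > q_range[1])
        )
    )
    eps_p = (p_range[1] - p_range[0]) * 1e-12
    eps_q = (q_range[1] - q_range[0]) * 1e-12
    pclip = np.clip(pooled[:, 0], p_range[0], p_range[1] - eps_p)
    qclip = np.clip(pooled[:, 1], q_range[0], q_range[1] - eps_q)
    counts, edges_p, edges_q = np.histogram2d(
        pclip, qclip, bins=n_bins, range=[p_range, q_range]
    )
    return PQHistogram(
        bin_edges_p=edges_p,
        bin_edges_q=edges_q,
        counts=counts.astype(np.int64),
        n_total=int(pooled.shape[0]),
        n_clipped=n_clipped,
    )


def weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Lower weighted median: smallest value whose cumulative weight reaches
    half of the total."""
    order = np.argsort(values, kind="stable")
    v = np.asarray(values, float)[order]
    w = np.asarray(weights, float)[order]
    cum = np.cumsum(w)
    return float(v[np.searchsorted(cum, 0.5 * cum[-1])])


def _weighted_quantile(values: np.ndarray, weights: np.ndarray, prob: float) -> float:
    order = np.argsort(values, kind="stable")
    v = np.asarray(values, float)[order]
    w = np.asarray(weights, float)[order]
    cum = np.cumsum(w)
    return float(v[np.searchsorted(cum, prob * cum[-1], side="left").clip(0, len(v) - 1)])


def _objective(points, weights, centroids, labels) -> float:
    diffs = points - centroids[labels]
    return float(np.sum(weights * np.hypot(diffs[:, 0], diffs[:, 1])))


def _grid_init(points, weights, k) -> np.ndarray:
    """Deterministic init at a grid of marginal weighted quantiles.

    For k = g*g the grid is g x g at probabilities (2i+1)/(2g); otherwise the
    first k nodes of the next-larger square grid are used.
    """
    g = int(np.ceil(np.sqrt(k)))
    probs = (2 * np.arange(g) + 1) / (2 * g)
    pq_nodes = [
        (_weighted_quantile(points[:, 0], weights, pp), _weighted_quantile(points[:, 1], weights, pg))
        for pp in probs
        for pg in probs
    ]
    init = np.array(pq_nodes[:k], dtype=float)
    # collapse duplicates onto distinct occupied bins so all k seeds differ
    if len(np.unique(init, axis=0)) < k:
        uniq = np.unique(points, axis=0)
        take = uniq[np.linspace(0, len(uniq) - 1, k).astype(int)]
        if len(np.unique(take, axis=0)) == k:
            init = take
    return init


def _lloyd(points, weights, init, tol, max_iter):
    """Alternating assignment / weighted-median update from one start.

    Every recorded state pairs a Voronoi assignment with the count-weighted
    coordinate-wise medians of its clusters, so the objective is always a
    genuine partition cost; the loop stops as soon as the partition cost
    fails to decrease, which keeps the trace non-increasing.
    """
    centroids = np.array(init, dtype=float)
    k = centroids.shape[0]
    trace: list[float] = []
    prev_cost = np.inf
    state = None
    for iteration in range(1, max_iter + 1):
        d = cdist(points, centroids)
        labels = d.argmin(axis=1)
        # reseed empty clusters at the point farthest from its own centroid
        for c in range(k):
            if not np.any(labels == c):
                far = np.argmax(d[np.arange(len(points)), labels])
                centroids[c] = points[far]
                d = cdist(points, centroids)
                labels = d.argmin(axis=1)
        medians = np.empty_like(centroids)
        for c in range(k):
            sel = labels == c
            medians[c, 0] = weighted_median(points[sel, 0], weights[sel])
            medians[c, 1] = weighted_median(points[sel, 1], weights[sel])
        cost = _objective(points, weights, medians, labels)
        if cost >= prev_cost - 1e-12 * max(1.0, abs(prev_cost)):
            break  # no improvement: keep the previous partition
        trace.append(cost)
        state = (medians, labels, cost, iteration)
        prev_cost = cost
        shift = float(np.abs(medians - centroids).max())
        centroids = medians
        if shift <= tol:
            break
    medians, labels, cost, iteration = state
    return medians, labels, cost, iteration, trace


def kmedians_fit(
    hist: PQHistogram,
    k: int = DEFAULT_K,
    tol: float = 1e-6,
    max_iter: int = 500,
    init: str = "grid",
    seed: int | None = None,
    n_restarts: int = 8,
    standardize: bool = False,
    exhaustive_limit: int = 2000,
) -> DsegModel:
    """Fit k segment centroids to the occupied histogram bins.

    ``init`` is one of ``"grid"`` (deterministic marginal-quantile grid,
    the default), ``"random"`` (seeded count-weighted restarts) or
    ``"exhaustive"`` (Lloyd from every k-subset of occupied bins; only
    feasible for tiny histograms).  Tiny problems — where the number of
    k-subsets does not exceed ``exhaustive_limit`` — are always solved
    exhaustively so the returned cost is the global partition minimum.
    """
    points, weights = hist.nonzero_bin_centers()
    n = len(points)
    if n < k:
        raise ValueError(f"degenerate histogram: {n} nonzero bins < k={k}")

    scale = np.ones(2)
    if standardize:
        mean = np.average(points, axis=0, weights=weights)
        var = np.average((points - mean) ** 2, axis=0, weights=weights)
        scale = np.where(var > 0, np.sqrt(var), 1.0)
    pts = points / scale

    from math import comb

    n_subsets = comb(n, k)
    runs: list[tuple] = []
    if init == "exhaustive" or n_subsets <= exhaustive_limit:
        uniq = pts
        for combo in combinations(range(n), k):
            runs.append(_lloyd(pts, weights, uniq[list(combo)], tol, max_iter))
        seed_policy = {"init": "exhaustive", "n_starts": n_subsets}
    elif init == "grid":
        runs.append(_lloyd(pts, weights, _grid_init(pts, weights, k), tol, max_iter))
        seed_policy = {"init": "grid", "quantile_probs": "(2i+1)/(2*ceil(sqrt(k)))"}
    elif init == "random":
        rng = np.random.default_rng(seed)
        prob = weights / weights.sum()
        for _ in range(n_restarts):
            idx = rng.choice(n, size=k, replace=False, p=prob)
            runs.append(_lloyd(pts, weights, pts[idx], tol, max_iter))
        seed_policy = {"init": "random", "seed": seed, "n_restarts": n_restarts}
    else:
        raise ValueError(f"unknown init {init!r}")

    centroids, labels, obj, n_iter, trace = min(runs, key=lambda r: r[2])
    if np.any(np.diff(trace) > 1e-9 * max(1.0, trace[0])):
        raise AssertionError("k-medians objective increased between iterations")
    centroids = centroids * scale

    order = canonical_segment_order(centroids)
    centroids = centroids[order]
    if standardize:
        # objective was computed in scaled coordinates; restate it in raw units
        raw_labels = cdist(points, centroids).argmin(axis=1)
        obj = _objective(points, weights, centroids, raw_labels)
    return DsegModel(
        centroids=centroids,
        canonical_order=order,
        objective=obj,
        n_iterations=n_iter,
        seed_policy={**seed_policy, "standardize": standardize, "tol": tol},
        objective_trace=trace,
    )


def canonical_segment_order(centroids: np.ndarray) -> np.ndarray:
    """Permutation ordering centroids by ascending p, ties by descending q."""
    c = np.asarray(centroids, dtype=float)
    return np.lexsort((-c[:, 1], c[:, 0]))


def assign_segments(
    pq: PQVolume, model: DsegModel, chunk: int = 1_000_000
) -> SegmentLabelVolume:
    """Label every in-mask voxel with its Euclidean-nearest centroid.

    Ties go to the lowest canonical index (argmin keeps the first minimum).
    """
    labels = np.zeros(pq.mask.shape, dtype=np.int32)
    points = pq.masked_points()
    out = np.empty(len(points), dtype=np.int32)
    for start in range(0, len(points), chunk):
        block = points[start : start + chunk]
        out[start : start + chunk] = cdist(block, model.centroids).argmin(axis=1) + 1
    labels[pq.mask] = out
    return SegmentLabelVolume(labels=labels, mask=pq.mask, k=model.k)
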