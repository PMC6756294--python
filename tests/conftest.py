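import numpy as np
import pytest

from dseg.cluster import PQHistogram
from dseg.spectra import DsegSpectrum


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_histogram_from_points(points, counts, n_bins=(64, 64)):
    """Histogram whose occupied bins coincide with the given points.

    Builds a grid wide enough to isolate each point in its own bin; used by
    clustering tests that need exact control over bin centres.
    """
    points = np.asarray(points, dtype=float)
    counts = np.asarray(counts, dtype=int)
    lo = points.min(axis=0) - 1.0
    hi = points.max(axis=0) + 1.0
    edges_p = np.linspace(lo[0], hi[0], n_bins[0] + 1)
    edges_q = np.linspace(lo[1], hi[1], n_bins[1] + 1)
    grid = np.zeros((n_bins[0], n_bins[1]), dtype=np.int64)
    for (p, q), c in zip(points, counts):
        ip = min(np.searchsorted(edges_p, p, side="right") - 1, n_bins[0] - 1)
        iq = min(np.searchsorted(edges_q, q, side="right") - 1, n_bins[1] - 1)
        grid[ip, iq] += c
    return PQHistogram(
        bin_edges_p=edges_p, bin_edges_q=edges_q, counts=grid, n_total=int(counts.sum())
    )


def spectrum(values, subject_id="s", visit_time=0.0):
    values = np.asarray(values, dtype=float)
    values = 100.0 * values / values.sum()
    return DsegSpectrum(values=values, subject_id=subject_id, visit_time=visit_time, n_voxels=1000)


@pytest.fixture
def spectrum_factory():
    return spectrum
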