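"""Spectral-angle score against a healthy reference spectrum.

The angle between two spectra A and B is ``arccos(<A,B> / (|A| |B|))``;
spectra are non-negative, so the angle lies in [0, pi/2].  Zero means the
two scans share the same microstructural composition up to scale; larger
angles mean greater divergence.  The reference (vector A) is picked from a
pool of healthy spectra by a deterministic fixed-point procedure and is
then held fixed while every scan of every subject is scored against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from dseg.spectra import DsegSpectrum

__all__ = ["ThetaScore", "ReferenceSelection", "spectrum_angle", "select_reference", "theta_series"]


@dataclass
class ThetaScore:
    theta: float  # radians, in [0, pi/2]
    subject_id: str = ""
    visit_time: float = 0.0
    reference_id: str = ""

    @property
    def degrees(self) -> float:
        return float(np.degrees(self.theta))


@dataclass
class ReferenceSelection:
    reference_id: str
    reference_spectrum: DsegSpectrum
    n_iterations: int
    trace: list[str] = field(default_factory=list)


def _angle(a: np.ndarray, b: np.ndarray) -> float:
    """arccos of the normalised scalar product, evaluated through the chord
    length ``2 asin(|a/|a| - b/|b|| / 2)`` which is exact at 0 and keeps full
    precision for the small angles typical of similar spectra."""
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("undefined angle: zero spectrum vector")
    chord = np.linalg.norm(a / na - b / nb)
    return float(2.0 * np.arcsin(min(0.5 * chord, 1.0)))


def spectrum_angle(a: DsegSpectrum, b: DsegSpectrum) -> ThetaScore:
    """Angle between two spectra (symmetric, scale-invariant)."""
    return ThetaScore(
        theta=_angle(a.values, b.values),
        subject_id=b.subject_id,
        visit_time=b.visit_time,
        reference_id=a.subject_id,
    )


def select_reference(healthy_spectra, max_iter: int = 100) -> ReferenceSelection:
    """Pick the least-divergent member of a healthy pool by fixed-point iteration.

    Start from the element-wise median of the pool (renormalised to 100),
    choose the member with the smallest angle to it (ties broken by lowest
    subject id), adopt that member as the new prototype, and repeat until
    the chosen member repeats.  Deterministic given the pool.
    """
    pool = list(healthy_spectra)
    if not pool:
        raise ValueError("empty healthy pool")
    mat = np.array([s.values for s in pool])
    proto = np.median(mat, axis=0)
    if proto.sum() <= 0:
        proto = mat.mean(axis=0)
    proto = 100.0 * proto / proto.sum()

    trace: list[str] = []
    chosen_idx = -1
    for iteration in range(1, max_iter + 1):
        angles = np.array([_angle(proto, row) for row in mat])
        best = min(range(len(pool)), key=lambda i: (angles[i], str(pool[i].subject_id)))
        trace.append(str(pool[best].subject_id))
        if best == chosen_idx:
            break
        chosen_idx = best
        proto = mat[best]
    return ReferenceSelection(
        reference_id=str(pool[chosen_idx].subject_id),
        reference_spectrum=pool[chosen_idx],
        n_iterations=iteration,
        trace=trace,
    )


def theta_series(spectra, ref: ReferenceSelection) -> list[ThetaScore]:
    """Score every scan against the fixed reference spectrum."""
    a = ref.reference_spectrum.values
    return [
        ThetaScore(
            theta=_angle(a, s.values),
            subject_id=s.subject_id,
            visit_time=s.visit_time,
            reference_id=ref.reference_id,
        )
        for s in spectra
    ]
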