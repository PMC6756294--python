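"""Isotropic (p) and anisotropic (q) diffusion maps from tensor eigenvalues.

Every voxel of a diffusion tensor is reduced to two scalar magnitudes:

* ``p = sqrt(3) * MD`` — the magnitude of the isotropic part of the tensor,
* ``q = ||lambda - MD||`` — the magnitude of the deviatoric (anisotropic)
  part, i.e. the Euclidean norm of the eigenvalue deviations from the mean
  diffusivity ``MD = (l1 + l2 + l3) / 3``.

Both carry units of mm^2 s^-1 and locate the voxel in the 2-D (p, q) plane
that the clustering stage segments.  This module is the single place where
the (p, q) convention is defined; swap the formulas here to change it.

A log-linear ordinary-least-squares tensor fit is provided so synthetic
diffusion-weighted volumes can be consumed; real pipelines may enter at
:class:`EigenvalueVolume` directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DwiVolume",
    "EigenvalueVolume",
    "PQVolume",
    "InsufficientDirectionsError",
    "fit_tensor_loglinear",
    "compute_pq",
]


class InsufficientDirectionsError(ValueError):
    """Raised when a DWI set has fewer than 6 usable gradient directions."""


@dataclass
class DwiVolume:
    """A 4-D diffusion-weighted acquisition plus gradient table and mask.

    Parameters
    ----------
    signal : ndarray, shape (x, y, z, n_volumes)
        Non-negative diffusion-weighted signal, arbitrary units.
    bvals : ndarray, shape (n_volumes,)
        b-value per volume in s mm^-2.  At least one must be 0.
    bvecs : ndarray, shape (n_volumes, 3)
        Unit gradient direction per volume (ignored where b == 0).
    mask : ndarray of bool, shape (x, y, z)
    voxel_size : tuple of float
        Voxel edge lengths in mm.
    """

    signal: np.ndarray
    bvals: np.ndarray
    bvecs: np.ndarray
    mask: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.bvals = np.asarray(self.bvals, dtype=float).ravel()
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.signal.ndim != 4:
            raise ValueError("signal must be 4-D (x, y, z, volume)")
        n = self.signal.shape[3]
        if self.bvals.shape != (n,):
            raise ValueError("bvals length must match number of volumes")
        if self.bvecs.shape != (n, 3):
            raise ValueError("bvecs must have shape (n_volumes, 3)")
        if self.mask.shape != self.signal.shape[:3]:
            raise ValueError("mask shape must match the spatial grid")
        if not np.any(self.bvals == 0):
            raise ValueError("at least one b=0 volume is required")
        if np.any(self.signal < 0):
            raise ValueError("signal must be non-negative")
        dw = self.bvals > 0
        norms = np.linalg.norm(self.bvecs[dw], axis=1)
        if dw.any() and not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("bvecs with b>0 must have unit norm (tol 1e-6)")


@dataclass
class EigenvalueVolume:
    """Per-voxel sorted tensor eigenvalues (l1 >= l2 >= l3), mm^2 s^-1."""

    lambdas: np.ndarray  # (x, y, z, 3)
    mask: np.ndarray  # (x, y, z) bool
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lambdas = np.asarray(self.lambdas, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.lambdas.ndim != 4 or self.lambdas.shape[3] != 3:
            raise ValueError("lambdas must have shape (x, y, z, 3)")
        if self.mask.shape != self.lambdas.shape[:3]:
            raise ValueError("mask shape must match the spatial grid")
        inside = self.lambdas[self.mask]
        if inside.size and not np.all(np.isfinite(inside)):
            raise ValueError("eigenvalues must be finite within the mask")
        if inside.size and np.any(np.diff(inside, axis=1) > 1e-12):
            raise ValueError("eigenvalues must be sorted descending within the mask")


@dataclass
class PQVolume:
    """Isotropy (p) and anisotropy (q) magnitude maps, zero outside the mask."""

    p: np.ndarray
    q: np.ndarray
    mask: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        self.q = np.asarray(self.q, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if not (self.p.shape == self.q.shape == self.mask.shape):
            raise ValueError("p, q and mask must share one shape")

    def masked_points(self) -> np.ndarray:
        """Return the in-mask (p, q) pairs as an (n, 2) array."""
        return np.column_stack([self.p[self.mask], self.q[self.mask]])


def _design_matrix(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    gx, gy, gz = bvecs[:, 0], bvecs[:, 1], bvecs[:, 2]
    b = bvals
    return np.column_stack(
        [
            np.ones_like(b),
            -b * gx * gx,
            -b * gy * gy,
            -b * gz * gz,
            -2.0 * b * gx * gy,
            -2.0 * b * gx * gz,
            -2.0 * b * gy * gz,
        ]
    )


def _count_distinct_directions(bvals: np.ndarray, bvecs: np.ndarray, atol: float = 1e-6) -> int:
    """Distinct b>0 directions up to sign."""
    dirs = bvecs[bvals > 0]
    kept: list[np.ndarray] = []
    for d in dirs:
        if not any(
            np.allclose(d, e, atol=atol) or np.allclose(d, -e, atol=atol) for e in kept
        ):
            kept.append(d)
    return len(kept)


def fit_tensor_loglinear(dwi: DwiVolume, clamp_negative: bool = True) -> EigenvalueVolume:
    """Ordinary-least-squares tensor fit on log-signal.

    Voxels with non-positive signal in any volume are removed from the mask
    (their count is recorded in provenance), negative fitted eigenvalues are
    clamped to zero when ``clamp_negative`` (default, count recorded).

    Raises
    ------
    InsufficientDirectionsError
        If fewer than 6 distinct non-collinear gradient directions with b>0
        are available.
    """
    if _count_distinct_directions(dwi.bvals, dwi.bvecs) < 6:
        raise InsufficientDirectionsError(
            "insufficient directions: need >=6 distinct non-collinear b>0 directions"
        )
    X = _design_matrix(dwi.bvals, dwi.bvecs)
    if np.linalg.matrix_rank(X) < 7:
        raise InsufficientDirectionsError(
            "insufficient directions: gradient design matrix is rank deficient"
        )

    mask = dwi.mask.copy()
    sig = dwi.signal[mask]  # (n_vox, n_vol)
    positive = np.all(sig > 0, axis=1)
    n_excluded = int((~positive).sum())
    if n_excluded:
        idx = np.flatnonzero(mask.ravel())[~positive]
        flat = mask.ravel()
        flat[idx] = False
        mask = flat.reshape(dwi.mask.shape)
        sig = sig[positive]

    lambdas = np.zeros(dwi.mask.shape + (3,), dtype=float)
    if sig.shape[0]:
        coef, *_ = np.linalg.lstsq(X, np.log(sig).T, rcond=None)
        dxx, dyy, dzz, dxy, dxz, dyz = coef[1:7]
        tensors = np.empty((sig.shape[0], 3, 3), dtype=float)
        tensors[:, 0, 0] = dxx
        tensors[:, 1, 1] = dyy
        tensors[:, 2, 2] = dzz
        tensors[:, 0, 1] = tensors[:, 1, 0] = dxy
        tensors[:, 0, 2] = tensors[:, 2, 0] = dxz
        tensors[:, 1, 2] = tensors[:, 2, 1] = dyz
        eig = np.linalg.eigvalsh(tensors)[:, ::-1]  # descending
        n_clamped = int(np.sum(eig < 0))
        if clamp_negative:
            eig = np.clip(eig, 0.0, None)
            eig = -np.sort(-eig, axis=1)
        lambdas[mask] = eig
    else:
        n_clamped = 0

    return EigenvalueVolume(
        lambdas=lambdas,
        mask=mask,
        voxel_size=dwi.voxel_size,
        provenance={
            "estimator": "ols_loglinear",
            "n_excluded_nonpositive_signal": n_excluded,
            "n_clamped_eigenvalues": n_clamped,
            "clamp_policy": "clip_to_zero" if clamp_negative else "none",
        },
    )


def compute_pq(eig: EigenvalueVolume, clamp_negative: bool = True) -> PQVolume:
    """Map sorted eigenvalues to (p, q) magnitudes per voxel.

    ``p = sqrt(3) * MD`` and ``q`` is the Euclidean norm of the deviatoric
    eigenvalues; both depend only on the tensor spectrum, so the result is
    invariant to any rotation of the tensor.
    """
    lam = eig.lambdas.copy()
    n_clamped = int(np.sum(lam[eig.mask] < 0))
    if clamp_negative and n_clamped:
        lam = np.clip(lam, 0.0, None)
    md = lam.mean(axis=3)
    p = np.sqrt(3.0) * md
    q = np.sqrt(np.sum((lam - md[..., None]) ** 2, axis=3))
    p = np.where(eig.mask, p, 0.0)
    q = np.where(eig.mask, q, 0.0)
    prov = dict(eig.provenance)
    prov.update({"pq_clamped_voxels": n_clamped, "pq_convention": "p=sqrt3*MD,q=|deviatoric|"})
    return PQVolume(p=p, q=q, mask=eig.mask, provenance=prov)
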