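"""Shared readers/writers: NIfTI-1 volumes, FSL-style gradient tables,
tidy TSV tables, and the run manifest."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd


__all__ = [
    "read_volume",
    "write_volume",
    "read_bvals_bvecs",
    "write_spectra_tsv",
    "read_spectra_tsv",
    "write_theta_tsv",
    "RunManifest",
    "config_hash",
]


def read_volume(path) -> tuple[np.ndarray, np.ndarray, tuple[float, ...]]:
    """Load a NIfTI-1 volume; returns (data, affine, voxel_size).

    Works identically for .nii and .nii.gz.  A malformed or truncated file
    raises a ValueError naming the path.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
    except Exception as exc:  # nibabel raises several header error types
        raise ValueError(f"malformed NIfTI file {path}: {exc}") from exc
    voxel_size = tuple(float(v) for v in img.header.get_zooms()[:3])
    return data, img.affine, voxel_size


def write_volume(path, data: np.ndarray, affine: np.ndarray | None = None) -> None:
    if affine is None:
        affine = np.eye(4)
    nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))


def read_bvals_bvecs(bvals_path, bvecs_path) -> tuple[np.ndarray, np.ndarray, str]:
    """Read whitespace-delimited b-values and gradient directions.

    Accepts both FSL layouts — one row per volume or one column per volume —
    auto-detected from the shapes; the detected layout is returned for
    provenance.
    """
    bvals = np.loadtxt(bvals_path, ndmin=2)
    bvecs = np.loadtxt(bvecs_path, ndmin=2)
    bvals = bvals.ravel()
    n = len(bvals)
    if bvecs.shape == (3, n):
        layout = "rows_per_axis"
        bvecs = bvecs.T
    elif bvecs.shape == (n, 3):
        layout = "rows_per_volume"
    else:
        raise ValueError(
            f"bvecs shape {bvecs.shape} incompatible with {n} b-values"
        )
    return bvals, bvecs, layout


def write_spectra_tsv(path, spectra) -> None:
    rows = []
    for s in spectra:
        row = {"subject_id": s.subject_id, "visit_time": s.visit_time, "n_voxels": s.n_voxels}
        row.update({f"s{i + 1:02d}": v for i, v in enumerate(s.values)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_spectra_tsv(path):
    from dseg.spectra import DsegSpectrum

    df = pd.read_csv(path, sep="\t")
    seg_cols = [c for c in df.columns if c.startswith("s") and c[1:].isdigit()]
    return [
        DsegSpectrum(
            values=row[seg_cols].to_numpy(float),
            subject_id=str(row["subject_id"]),
            visit_time=float(row["visit_time"]),
            n_voxels=int(row["n_voxels"]),
        )
        for _, row in df.iterrows()
    ]


def write_theta_tsv(path, scores) -> None:
    pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in scores],
            "visit_time": [s.visit_time for s in scores],
            "theta_rad": [s.theta for s in scores],
            "reference_id": [s.reference_id for s in scores],
        }
    ).to_csv(path, sep="\t", index=False)


def config_hash(config: dict) -> str:
    """Stable hash of a JSON-serialisable configuration mapping."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    """Record of an executed pipeline run: stages, outputs, seed, hashes."""

    config_hash: str
    seed: int
    version: str = ""
    stages: list[dict] = field(default_factory=list)
    created: float = field(default_factory=time.time)

    def add_stage(self, name: str, outputs: list[str], **info) -> None:
        self.stages.append({"name": name, "outputs": [str(o) for o in outputs], **info})

    def validate(self) -> None:
        for stage in self.stages:
            for out in stage["outputs"]:
                if not Path(out).exists():
                    raise FileNotFoundError(f"stage {stage['name']} output missing: {out}")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "config_hash": self.config_hash,
                    "seed": self.seed,
                    "version": self.version,
                    "stages": self.stages,
                    "created": self.created,
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "RunManifest":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(**payload)
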