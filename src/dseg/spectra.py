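"""Per-scan segment spectra and tissue-class summaries.

A spectrum is the percentage of cerebrum volume falling in each of the k
segments (canonical order); it always sums to 100.  Tissue-class summaries
regroup segments into GM / WM / CSF / borderline / lesion-related classes
for display — they never feed the angle metric.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from dseg.cluster import DEFAULT_K, DsegModel, SegmentLabelVolume

__all__ = [
    "DsegSpectrum",
    "TissueClassMap",
    "compute_spectrum",
    "tissue_class_summary",
    "default_tissue_class_map",
    "TISSUE_CLASSES",
]

TISSUE_CLASSES = ("GM", "WM", "CSF", "GM/CSF-borderline", "WMH-related")


@dataclass
class DsegSpectrum:
    """A k-component percentage vector summarising one scan."""

    values: np.ndarray
    subject_id: str = ""
    visit_time: float = 0.0
    n_voxels: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("spectrum values must be a 1-D vector")
        if np.any(self.values < 0):
            raise ValueError("spectrum values must be non-negative")
        if abs(self.values.sum() - 100.0) > 1e-9:
            raise ValueError("spectrum must sum to 100")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class TissueClassMap:
    """Maps each canonical segment index (1-based) to one tissue class."""

    mapping: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for seg, cls in self.mapping.items():
            if cls not in TISSUE_CLASSES:
                raise ValueError(f"unknown tissue class {cls!r} for segment {seg}")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({str(k): v for k, v in self.mapping.items()}, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "TissueClassMap":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(mapping={int(k): v for k, v in raw.items()})


def compute_spectrum(
    labels: SegmentLabelVolume,
    subject_id: str = "",
    visit_time: float = 0.0,
) -> DsegSpectrum:
    """Percentage of in-mask voxels per canonical segment."""
    inside = labels.labels[labels.mask]
    if inside.size == 0:
        raise ValueError("empty scan: no in-mask voxels")
    counts = np.bincount(inside, minlength=labels.k + 1)[1 : labels.k + 1]
    values = 100.0 * counts / inside.size
    return DsegSpectrum(
        values=values, subject_id=subject_id, visit_time=visit_time, n_voxels=int(inside.size)
    )


def tissue_class_summary(spec: DsegSpectrum, class_map: TissueClassMap) -> dict[str, float]:
    """Sum spectrum percentages within each tissue class (totals 100)."""
    out: dict[str, float] = {}
    for seg_index, value in enumerate(spec.values, start=1):
        cls = class_map.mapping.get(seg_index)
        if cls is None:
            raise ValueError(f"segment {seg_index} is not mapped to a tissue class")
        out[cls] = out.get(cls, 0.0) + float(value)
    return out


def default_tissue_class_map(model: DsegModel) -> TissueClassMap:
    """Heuristic class map from centroid positions.

    Positions are normalised over the fitted centroids; high-q segments are
    called WM, high-p/low-q segments CSF, low-p/low-q GM, with lesion-related
    and borderline bands in between.  This is a display convention only and
    is intended to be overridden by a user-supplied map.
    """
    c = model.centroids
    p = (c[:, 0] - c[:, 0].min()) / max(np.ptp(c[:, 0]), 1e-30)
    q = (c[:, 1] - c[:, 1].min()) / max(np.ptp(c[:, 1]), 1e-30)
    mapping: dict[int, str] = {}
    for i in range(model.k):
        if q[i] >= 0.45:
            mapping[i + 1] = "WM"
        elif p[i] >= 0.75:
            mapping[i + 1] = "CSF"
        elif p[i] >= 0.55:
            mapping[i + 1] = "GM/CSF-borderline"
        elif p[i] >= 0.35:
            mapping[i + 1] = "WMH-related"
        else:
            mapping[i + 1] = "GM"
    return TissueClassMap(mapping=mapping)
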