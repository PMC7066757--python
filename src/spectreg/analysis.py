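"""Radiotracer-uptake normalization, difference maps and cohort aggregates.

Absolute tracer uptake differs between subjects and sessions through dose
and metabolization, so each SPECT volume is divided by its mean uptake in a
fixed reference box: 35 x 20 x 3 voxels (2100 voxels at the common
0.98 x 0.98 x 3 mm grid), centred in-plane on the femoral knee centre (FKC)
and placed 10 cm distally along z, in the tibial shaft region away from the
joint.  Normalized post-operative minus pre-operative uptake then gives a
per-subject voxel-wise difference map, and averaging co-registered
difference maps over subjects gives the cohort aggregate map.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .image import VolumetricImage

__all__ = [
    "NormalizationROI",
    "DifferenceMap",
    "AggregateMap",
    "DEFAULT_ROI_DIMS",
    "DEFAULT_ROI_OFFSET_MM",
    "build_normalization_roi",
    "normalize_uptake",
    "difference_map",
    "aggregate_map",
]

DEFAULT_ROI_DIMS = (35, 20, 3)
DEFAULT_ROI_OFFSET_MM = 100.0


@dataclass
class NormalizationROI:
    """Rectangular normalization box on the resampled grid."""

    lower: tuple[int, int, int]
    upper: tuple[int, int, int]
    grid_shape: tuple[int, int, int]
    anchor: tuple[float, float, float]
    offset_mm: float

    @property
    def voxel_count(self) -> int:
        return int(np.prod([u - l for l, u in zip(self.lower, self.upper)]))

    @property
    def slices(self):
        return tuple(slice(l, u) for l, u in zip(self.lower, self.upper))

    def mask(self) -> np.ndarray:
        m = np.zeros(self.grid_shape, dtype=bool)
        m[self.slices] = True
        return m


def build_normalization_roi(
    fkc,
    grid: VolumetricImage,
    dims_voxels=DEFAULT_ROI_DIMS,
    offset_mm: float = DEFAULT_ROI_OFFSET_MM,
) -> NormalizationROI:
    """Place the normalization box relative to the FKC landmark.

    The box is centred in-plane on the FKC's (x, y) voxel index and starts
    ``offset_mm`` along +z (distal); ``offset_mm = 0`` centres it on the
    FKC's slice.
    """
    fkc = np.asarray(fkc, dtype=float).reshape(3)
    dims = np.asarray(dims_voxels, dtype=int)
    if np.any(dims < 1):
        raise ValueError(f"box dimensions must be >= 1, got {dims_voxels}")
    anchor = fkc + np.array([0.0, 0.0, float(offset_mm)])
    idx = np.rint(grid.world_to_index(anchor)).astype(int)
    lower = idx - dims // 2
    upper = lower + dims
    shape = np.asarray(grid.shape)
    if np.any(lower < 0) or np.any(upper > shape):
        raise ValueError(
            f"normalization box [{lower.tolist()}, {upper.tolist()}) exits the grid "
            f"{tuple(shape)}; use a smaller z offset or box"
        )
    return NormalizationROI(
        tuple(lower.tolist()),
        tuple(upper.tolist()),
        tuple(grid.shape),
        tuple(fkc.tolist()),
        float(offset_mm),
    )


def normalize_uptake(spect: VolumetricImage, roi: NormalizationROI) -> VolumetricImage:
    """Divide every voxel by the mean uptake inside the ROI (ROI mean becomes 1)."""
    if tuple(spect.shape) != roi.grid_shape:
        raise ValueError(
            f"SPECT grid {spect.shape} does not match the ROI grid {roi.grid_shape}"
        )
    mean = float(np.asarray(spect.voxels, dtype=float)[roi.slices].mean())
    if mean <= 0:
        raise ValueError(f"ROI mean uptake is {mean}; cannot normalize")
    return spect.with_voxels(np.asarray(spect.voxels, dtype=float) / mean)


@dataclass
class DifferenceMap:
    """Voxel-wise post-minus-pre normalized uptake on a reference grid."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    subject_id: str = "subject"
    valid: np.ndarray | None = None  # False where the subject has no data
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.valid is None:
            self.valid = np.ones(self.values.shape, dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.shape != self.values.shape:
            raise ValueError("valid mask must be congruent with the value grid")


def difference_map(
    post_norm: VolumetricImage,
    pre_norm_in_post_space: VolumetricImage,
    subject_id: str = "subject",
    valid: np.ndarray | None = None,
    provenance: dict | None = None,
) -> DifferenceMap:
    """Voxel-wise post - pre of two normalized SPECT volumes on one grid."""
    if post_norm.shape != pre_norm_in_post_space.shape:
        raise ValueError(
            f"grid mismatch: post {post_norm.shape} vs pre {pre_norm_in_post_space.shape}"
        )
    if post_norm.spacing != pre_norm_in_post_space.spacing:
        raise ValueError(
            f"spacing mismatch: {post_norm.spacing} vs {pre_norm_in_post_space.spacing}"
        )
    diff = np.asarray(post_norm.voxels, dtype=float) - np.asarray(
        pre_norm_in_post_space.voxels, dtype=float
    )
    return DifferenceMap(
        diff,
        post_norm.spacing,
        post_norm.origin,
        subject_id=subject_id,
        valid=valid,
        provenance=provenance or {},
    )


@dataclass
class AggregateMap:
    """Cohort mean difference with a per-voxel contributing-subject count.

    The standard-deviation companion volume supports exploratory statistical
    mapping and is an extension beyond the plain mean.
    """

    mean: np.ndarray
    count: np.ndarray
    std: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    subject_ids: tuple = ()


def aggregate_map(maps: list[DifferenceMap]) -> AggregateMap:
    """Voxel-wise mean over subjects' difference maps on a common grid.

    Voxels outside a subject's valid extent are excluded from that voxel's
    mean; the per-voxel count records how many subjects contributed.
    """
    if not maps:
        raise ValueError("need at least one difference map")
    first = maps[0]
    for m in maps[1:]:
        if m.values.shape != first.values.shape or m.spacing != first.spacing:
            raise ValueError("all difference maps must share the reference grid")
    stack = np.stack([m.values for m in maps])
    valid = np.stack([m.valid for m in maps])
    count = valid.sum(axis=0)
    safe = np.maximum(count, 1)
    total = np.where(valid, stack, 0.0).sum(axis=0)
    mean = total / safe
    var = np.where(valid, (stack - mean) ** 2, 0.0).sum(axis=0) / safe
    return AggregateMap(
        mean=np.where(count > 0, mean, 0.0),
        count=count,
        std=np.sqrt(var),
        spacing=first.spacing,
        origin=first.origin,
        subject_ids=tuple(m.subject_id for m in maps),
    )
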