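"""Landmark-driven VOI construction and threshold-based bone/prosthesis masking.

The knee is split into three cuboidal volumes of interest (femur, tibia,
patella), each defined as the axis-aligned bounding box of its bony landmarks
expanded by a configurable margin.  Within each VOI an intensity threshold
isolates bony tissue; in post-operative scans voxels at metal intensity are
additionally excluded (after a small dilation to swallow residual streak
artefacts) so the prosthesis cannot drive the registration.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image import (
    FEMUR_LANDMARKS,
    PATELLA_LANDMARKS,
    TIBIA_LANDMARKS,
    LandmarkSet,
    VolumetricImage,
)

__all__ = [
    "VOIBox",
    "BoneMask",
    "VOI_LANDMARKS",
    "build_voi",
    "crop",
    "segment_bone",
    "full_grid_mask",
    "DEFAULT_BONE_LOW_HU",
    "DEFAULT_PROSTHESIS_LOW_HU",
    "DEFAULT_MARGIN_MM",
    "DEFAULT_PROSTHESIS_DILATION",
]

#: Landmark subsets required to build each bone's VOI.  The fibula head is
#: grouped with the femur and the femoral knee centre with the tibia,
#: following the platform's landmark protocol (override via ``landmark_names``
#: in :func:`build_voi` if a different grouping is preferred).
VOI_LANDMARKS = {
    "femur": FEMUR_LANDMARKS,
    "tibia": TIBIA_LANDMARKS,
    "patella": PATELLA_LANDMARKS,
}

DEFAULT_BONE_LOW_HU = 200.0
DEFAULT_PROSTHESIS_LOW_HU = 2500.0
DEFAULT_MARGIN_MM = (20.0, 20.0, 20.0)
#: (in-plane voxels, in-plane voxels, slices) dilation of the metal mask.
DEFAULT_PROSTHESIS_DILATION = (2, 2, 1)


@dataclass(frozen=True)
class VOIBox:
    """Cuboidal crop region in voxel indices: inclusive lower, exclusive upper."""

    bone: str
    lower: tuple[int, int, int]
    upper: tuple[int, int, int]

    def __post_init__(self):
        if any(u <= l for l, u in zip(self.lower, self.upper)):
            raise ValueError(f"degenerate VOI box lower={self.lower} upper={self.upper}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(u - l for l, u in zip(self.lower, self.upper))

    @property
    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(l, u) for l, u in zip(self.lower, self.upper))


@dataclass
class BoneMask:
    """Binary bone mask congruent with a cropped VOI image."""

    mask: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    bone: str = "femur"
    prosthesis_excluded: bool = False
    empty: bool = False

    def __post_init__(self):
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3-D")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self):
        return self.mask.shape

    @property
    def voxel_count(self) -> int:
        if not hasattr(self, "_voxel_count"):
            self._voxel_count = int(self.mask.sum())
        return self._voxel_count

    def bbox_index(self) -> tuple[np.ndarray, np.ndarray]:
        """(min, max) voxel indices of the mask support (cached; mask is
        treated as immutable once constructed)."""
        if not hasattr(self, "_bbox"):
            idx = np.argwhere(self.mask)
            if idx.size == 0:
                raise ValueError("empty mask has no bounding box")
            self._bbox = (idx.min(axis=0), idx.max(axis=0))
        return self._bbox

    def index_to_world(self, index) -> np.ndarray:
        return np.asarray(self.origin) + np.asarray(index, dtype=float) * np.asarray(
            self.spacing
        )

    def center_of_mass_world(self) -> np.ndarray:
        idx = np.argwhere(self.mask)
        if idx.size == 0:
            raise ValueError("empty mask has no centre of mass")
        return self.index_to_world(idx.mean(axis=0))


def full_grid_mask(image: VolumetricImage, bone: str = "femur") -> BoneMask:
    """All-ones mask over an image grid (used when no masking is wanted)."""
    return BoneMask(
        np.ones(image.shape, dtype=bool), image.spacing, image.origin, bone=bone
    )


def build_voi(
    landmarks: LandmarkSet,
    bone: str,
    image: VolumetricImage,
    margin_mm=DEFAULT_MARGIN_MM,
    landmark_names=None,
) -> VOIBox:
    """Axis-aligned landmark bounding box expanded by ``margin_mm`` per side.

    The margin is converted to voxels (rounded up) per axis and the box is
    clamped to the image grid.
    """
    if bone not in VOI_LANDMARKS:
        raise ValueError(f"bone must be one of {sorted(VOI_LANDMARKS)}, got {bone!r}")
    names = tuple(landmark_names) if landmark_names is not None else VOI_LANDMARKS[bone]
    for name in names:
        if name not in landmarks:
            raise ValueError(f"missing landmark {name}")
    pts_idx = image.world_to_index(landmarks.as_array(names))
    margin_vox = np.ceil(np.asarray(margin_mm, dtype=float) / np.asarray(image.spacing)).astype(
        int
    )
    lower = np.floor(pts_idx.min(axis=0)).astype(int) - margin_vox
    upper = np.ceil(pts_idx.max(axis=0)).astype(int) + 1 + margin_vox
    lower = np.maximum(lower, 0)
    upper = np.minimum(upper, np.asarray(image.shape))
    if np.any(upper <= lower):
        raise ValueError(
            f"{bone} VOI is degenerate after clamping to the grid "
            f"(lower={lower.tolist()}, upper={upper.tolist()})"
        )
    return VOIBox(bone, tuple(lower.tolist()), tuple(upper.tolist()))


def crop(image: VolumetricImage, box: VOIBox) -> VolumetricImage:
    """Extract the VOI sub-grid, shifting the origin to preserve world coordinates."""
    shape = np.asarray(image.shape)
    if np.any(np.asarray(box.lower) < 0) or np.any(np.asarray(box.upper) > shape):
        raise ValueError(f"VOI box {box} exceeds grid {tuple(shape)}")
    voxels = image.voxels[box.slices].copy()
    origin = image.index_to_world(np.asarray(box.lower, dtype=float))
    return dataclasses.replace(image, voxels=voxels, origin=tuple(origin))


def segment_bone(
    ct_voi: VolumetricImage,
    bone_low: float = DEFAULT_BONE_LOW_HU,
    prosthesis_low: float = DEFAULT_PROSTHESIS_LOW_HU,
    bone: str = "femur",
    dilation: tuple[int, int, int] = DEFAULT_PROSTHESIS_DILATION,
) -> BoneMask:
    """Threshold a CT VOI into a bone mask, excluding the (dilated) prosthesis.

    Bone is ``bone_low <= HU < prosthesis_low``; voxels at or above
    ``prosthesis_low`` are treated as metal and removed together with a
    dilated halo of ``dilation`` voxels (in-plane, in-plane, slices).
    An all-empty result is flagged (``empty=True``) with a warning instead of
    raising; the registration driver refuses empty masks.
    """
    if ct_voi.modality != "CT":
        raise ValueError(f"bone segmentation expects CT input, got {ct_voi.modality}")
    if not bone_low < prosthesis_low:
        raise ValueError(f"bone_low ({bone_low}) must be below prosthesis_low ({prosthesis_low})")
    hu = np.asarray(ct_voi.voxels)
    mask = (hu >= bone_low) & (hu < prosthesis_low)
    metal = hu >= prosthesis_low
    prosthesis_excluded = bool(metal.any())
    if prosthesis_excluded:
        rx, ry, rz = dilation
        structure = np.ones((2 * rx + 1, 2 * ry + 1, 2 * rz + 1), dtype=bool)
        metal = ndimage.binary_dilation(metal, structure=structure)
        mask &= ~metal
    empty = not mask.any()
    if empty:
        warnings.warn(f"{bone} bone mask is empty at bone_low={bone_low} HU", stacklevel=2)
    return BoneMask(
        mask,
        ct_voi.spacing,
        ct_voi.origin,
        bone=bone,
        prosthesis_excluded=prosthesis_excluded,
        empty=empty,
    )
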