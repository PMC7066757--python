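"""Volumetric image data model and I/O.

Images live on regular axis-aligned grids in a world coordinate frame
measured in millimetres.  Grid axis 0 is the patient's medio-lateral (x)
direction, axis 1 antero-posterior (y), axis 2 proximo-distal (z), and the
world position of voxel index ``(i, j, k)`` is ``origin + index * spacing``.
Oblique acquisitions (non-identity direction cosines) are rejected at read
time: every transform downstream assumes this axis-aligned convention.
"""

from __future__ import annotations

import dataclasses
import os
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "VolumetricImage",
    "LandmarkSet",
    "PairedScan",
    "CANONICAL_LANDMARKS",
    "FEMUR_LANDMARKS",
    "TIBIA_LANDMARKS",
    "PATELLA_LANDMARKS",
    "read_image",
    "write_image",
    "read_landmarks",
    "write_landmarks",
    "read_paired_scan",
    "resample",
    "resampled_shape",
    "reflect_sagittal",
]

#: Default fill values used when resampling pushes samples outside the
#: source extent: air for CT, zero counts for SPECT.
BACKGROUND_FILL = {"CT": -1024.0, "SPECT": 0.0}

FEMUR_LANDMARKS = ("FibulaHead", "FTP", "FLE", "FME")
TIBIA_LANDMARKS = ("FKC", "TibiaLateralPeak", "TibiaMedialPeak")
PATELLA_LANDMARKS = ("ProximalMargin", "DistalMargin", "LateralMargin", "MedialMargin")
CANONICAL_LANDMARKS = FEMUR_LANDMARKS + TIBIA_LANDMARKS + PATELLA_LANDMARKS


@dataclass
class VolumetricImage:
    """A scalar 3-D image on a regular grid.

    Parameters
    ----------
    voxels
        Array of shape ``(nx, ny, nz)``.
    spacing
        Per-axis voxel size in mm, strictly positive.
    origin
        World position (mm) of voxel ``(0, 0, 0)``.
    modality
        ``"CT"`` (Hounsfield units) or ``"SPECT"`` (counts).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    modality: str = "CT"

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3-D voxel grid, got ndim={self.voxels.ndim}")
        if min(self.voxels.shape) < 1:
            raise ValueError(f"grid dimensions must be >= 1, got {self.voxels.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)
        if self.modality not in ("CT", "SPECT"):
            raise ValueError(f"modality must be 'CT' or 'SPECT', got {self.modality!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def units(self) -> str:
        return "HU" if self.modality == "CT" else "counts"

    @property
    def background(self) -> float:
        return BACKGROUND_FILL[self.modality]

    @property
    def extent_mm(self) -> np.ndarray:
        """Physical extent covered by the grid (dimension * spacing) per axis."""
        return np.asarray(self.shape) * np.asarray(self.spacing)

    def index_to_world(self, index) -> np.ndarray:
        """World coordinates (mm) of fractional voxel indices, shape (..., 3)."""
        index = np.asarray(index, dtype=float)
        return np.asarray(self.origin) + index * np.asarray(self.spacing)

    def world_to_index(self, world) -> np.ndarray:
        """Fractional voxel indices of world coordinates (mm), shape (..., 3)."""
        world = np.asarray(world, dtype=float)
        return (world - np.asarray(self.origin)) / np.asarray(self.spacing)

    def center_world(self) -> np.ndarray:
        """World position of the grid centre (mm)."""
        return self.index_to_world((np.asarray(self.shape) - 1) / 2.0)

    def with_voxels(self, voxels: np.ndarray) -> "VolumetricImage":
        return dataclasses.replace(self, voxels=voxels)


@dataclass
class LandmarkSet:
    """Named anatomical landmarks in world mm coordinates."""

    points: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        clean: dict[str, np.ndarray] = {}
        for name, xyz in self.points.items():
            xyz = np.asarray(xyz, dtype=float).reshape(3)
            if not np.all(np.isfinite(xyz)):
                raise ValueError(f"landmark {name!r} has non-finite coordinates {xyz}")
            if name not in CANONICAL_LANDMARKS:
                raise ValueError(
                    f"unknown landmark {name!r}; valid names: {', '.join(CANONICAL_LANDMARKS)}"
                )
            clean[name] = xyz
        self.points = clean

    def __getitem__(self, name: str) -> np.ndarray:
        return self.points[name]

    def __contains__(self, name: str) -> bool:
        return name in self.points

    def names(self) -> list[str]:
        return list(self.points)

    def subset(self, names) -> "LandmarkSet":
        missing = [n for n in names if n not in self.points]
        if missing:
            raise KeyError(f"missing landmark {missing[0]}")
        return LandmarkSet({n: self.points[n] for n in names})

    def as_array(self, names=None) -> np.ndarray:
        names = list(names) if names is not None else self.names()
        return np.stack([self.points[n] for n in names])

    def map(self, fn) -> "LandmarkSet":
        """Apply a world-point mapping (array (N,3) -> (N,3)) to all landmarks."""
        names = self.names()
        if not names:
            return LandmarkSet({})
        mapped = fn(self.as_array(names))
        return LandmarkSet({n: mapped[i] for i, n in enumerate(names)})


@dataclass
class PairedScan:
    """One subject/timepoint: CT and SPECT volumes sharing a world frame."""

    ct: VolumetricImage
    spect: VolumetricImage
    landmarks: LandmarkSet
    laterality: str = "L"
    timepoint: str = "preop"
    subject_id: str = "subject"

    def __post_init__(self):
        if self.laterality not in ("L", "R"):
            raise ValueError(f"laterality must be 'L' or 'R', got {self.laterality!r}")
        if self.timepoint not in ("preop", "postop"):
            raise ValueError(f"timepoint must be 'preop' or 'postop', got {self.timepoint!r}")
        if self.ct.spacing == self.spect.spacing:
            d = np.abs(np.asarray(self.ct.origin) - np.asarray(self.spect.origin))
            if np.any(d > 1.0):
                warnings.warn(
                    f"CT and SPECT origins differ by {d} mm (> 1 mm); the two modalities "
                    "are assumed to share one patient frame",
                    stacklevel=2,
                )
        else:
            # Different grids can have legitimately different origins; compare
            # grid centres with a one-coarse-voxel tolerance instead.
            d = np.abs(self.ct.center_world() - self.spect.center_world())
            tol = max(max(self.ct.spacing), max(self.spect.spacing))
            if np.any(d > tol):
                warnings.warn(
                    f"CT and SPECT grid centres differ by {d} mm; the two modalities "
                    "are assumed to share one patient frame",
                    stacklevel=2,
                )


# ---------------------------------------------------------------------------
# I/O


def _nifti_affine(image: VolumetricImage) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = image.spacing
    aff[:3, 3] = image.origin
    return aff


def write_image(image: VolumetricImage, path) -> None:
    """Write a volume as NIfTI-1 (.nii or .nii.gz), preserving spacing/origin."""
    import nibabel as nib

    path = Path(path)
    if path.suffix not in (".nii", ".gz"):
        raise ValueError(f"unsupported output format {path.name!r}; use .nii or .nii.gz")
    img = nib.Nifti1Image(np.asarray(image.voxels), _nifti_affine(image))
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))


def _check_axis_aligned(affine: np.ndarray, path) -> None:
    off = affine[:3, :3].copy()
    np.fill_diagonal(off, 0.0)
    if np.max(np.abs(off)) > 1e-4 or np.any(np.diag(affine[:3, :3]) <= 0):
        raise ValueError(
            f"{path}: image has non-identity direction cosines (oblique or flipped "
            "acquisition); only axis-aligned volumes are supported"
        )


def _read_nifti(path, modality: str) -> VolumetricImage:
    import nibabel as nib

    img = nib.load(str(path))
    affine = img.affine
    _check_axis_aligned(affine, path)
    voxels = np.asarray(img.dataobj)
    spacing = tuple(float(affine[i, i]) for i in range(3))
    origin = tuple(float(affine[i, 3]) for i in range(3))
    return VolumetricImage(voxels, spacing, origin, modality)


def _read_dicom_series(directory, modality: str) -> VolumetricImage:
    import pydicom

    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.suffix.lower() in (".dcm", ".ima", ""))
    files = [p for p in files if p.is_file()]
    if not files:
        raise ValueError(f"{directory}: no DICOM files found")
    slices = []
    for p in files:
        try:
            ds = pydicom.dcmread(str(p))
        except Exception as exc:  # pragma: no cover - corrupt input
            raise ValueError(f"{p}: unreadable DICOM file ({exc})") from exc
        slices.append((p, ds))
    ref_path, ref = slices[0]
    ref_ps = tuple(float(v) for v in ref.PixelSpacing)
    for p, ds in slices[1:]:
        if tuple(float(v) for v in ds.PixelSpacing) != ref_ps:
            raise ValueError(
                f"{p}: inconsistent PixelSpacing within series "
                f"({tuple(float(v) for v in ds.PixelSpacing)} vs {ref_ps} in {ref_path})"
            )
    iop = [float(v) for v in getattr(ref, "ImageOrientationPatient", [1, 0, 0, 0, 1, 0])]
    if not np.allclose(iop, [1, 0, 0, 0, 1, 0], atol=1e-4):
        raise ValueError(f"{ref_path}: non-axial DICOM orientation {iop} is not supported")
    slices.sort(key=lambda t: float(t[1].ImagePositionPatient[2]))
    zs = np.array([float(ds.ImagePositionPatient[2]) for _, ds in slices])
    if len(zs) > 1:
        dz = np.diff(zs)
        if np.max(dz) - np.min(dz) > 1e-3:
            bad = slices[int(np.argmax(np.abs(dz - np.median(dz)))) + 1][0]
            raise ValueError(f"{bad}: irregular slice spacing within series")
        slice_thickness = float(np.median(dz))
    else:
        slice_thickness = float(getattr(ref, "SliceThickness", 1.0))
    planes = []
    for _, ds in slices:
        arr = ds.pixel_array.astype(np.float32)
        arr = arr * float(getattr(ds, "RescaleSlope", 1.0)) + float(
            getattr(ds, "RescaleIntercept", 0.0)
        )
        # DICOM pixel arrays are (row=y, col=x); transpose to (x, y).
        planes.append(arr.T)
    voxels = np.stack(planes, axis=-1)
    ipp = [float(v) for v in slices[0][1].ImagePositionPatient]
    spacing = (ref_ps[1], ref_ps[0], slice_thickness)
    dicom_modality = str(getattr(ref, "Modality", "")).upper()
    if modality == "auto":
        modality = "CT" if dicom_modality == "CT" else "SPECT"
    return VolumetricImage(voxels, spacing, tuple(ipp), modality)


def read_image(path, modality: str = "auto") -> VolumetricImage:
    """Read a DICOM series directory or a NIfTI file.

    ``modality`` may be ``"CT"``, ``"SPECT"``, or ``"auto"`` (DICOM metadata;
    NIfTI has no modality tag, so ``auto`` defaults to CT).
    """
    path = Path(path)
    if path.is_dir():
        return _read_dicom_series(path, modality)
    if modality == "auto":
        modality = "CT"
    return _read_nifti(path, modality)


def read_landmarks(path) -> LandmarkSet:
    """Read landmarks from plain text: one ``NAME x y z`` (world mm) per line."""
    points = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 'NAME x y z', got {line!r}")
            name = parts[0]
            if name not in CANONICAL_LANDMARKS:
                raise ValueError(
                    f"{path}:{lineno}: unknown landmark {name!r}; valid names: "
                    f"{', '.join(CANONICAL_LANDMARKS)}"
                )
            points[name] = np.array([float(v) for v in parts[1:]])
    return LandmarkSet(points)


def write_landmarks(landmarks: LandmarkSet, path) -> None:
    with open(path, "w") as fh:
        for name in landmarks.names():
            x, y, z = landmarks[name]
            fh.write(f"{name} {x:.6f} {y:.6f} {z:.6f}\n")


def read_paired_scan(
    ct_path,
    spect_path,
    landmark_path,
    laterality: str = "L",
    timepoint: str = "preop",
    subject_id: str = "subject",
) -> PairedScan:
    """Load one subject/timepoint's CT + SPECT + landmarks from disk."""
    ct = read_image(ct_path, modality="CT" if not Path(ct_path).is_dir() else "auto")
    if ct.modality != "CT":
        raise ValueError(f"{ct_path}: expected a CT volume, metadata says {ct.modality}")
    spect = read_image(spect_path, modality="SPECT" if not Path(spect_path).is_dir() else "auto")
    if spect.modality != "SPECT":
        spect = dataclasses.replace(spect, modality="SPECT")
    landmarks = read_landmarks(landmark_path)
    return PairedScan(ct, spect, landmarks, laterality, timepoint, subject_id)


# ---------------------------------------------------------------------------
# Resampling and reflection

_ORDER = {"nearest": 0, "linear": 1, "cubic_bspline": 3}


def resampled_shape(shape, spacing_in, spacing_out) -> tuple[int, int, int]:
    """Output dimensions preserving physical extent: ceil(n * s_in / s_out)."""
    return tuple(
        int(np.ceil(n * si / so)) for n, si, so in zip(shape, spacing_in, spacing_out)
    )


def resample(
    image: VolumetricImage,
    target_spacing,
    interpolation: str = "linear",
    fill: float | None = None,
) -> VolumetricImage:
    """Resample onto a grid with ``target_spacing``, preserving origin and extent.

    Output voxel ``j`` samples the input at world position
    ``origin + j * target_spacing``; samples outside the source extent take the
    modality background fill (or ``fill`` when given).
    """
    if interpolation not in _ORDER:
        raise ValueError(f"interpolation must be one of {sorted(_ORDER)}, got {interpolation!r}")
    target_spacing = tuple(float(s) for s in target_spacing)
    if any(s <= 0 for s in target_spacing):
        raise ValueError(f"target spacing must be positive, got {target_spacing}")
    out_shape = resampled_shape(image.shape, image.spacing, target_spacing)
    ratio = np.asarray(target_spacing) / np.asarray(image.spacing)
    cval = image.background if fill is None else float(fill)
    out = ndimage.affine_transform(
        np.asarray(image.voxels, dtype=float),
        np.diag(ratio),
        offset=0.0,
        output_shape=out_shape,
        order=_ORDER[interpolation],
        mode="constant",
        cval=cval,
    )
    return VolumetricImage(out, target_spacing, image.origin, image.modality)


def _reflect_image(image: VolumetricImage, x_center: float) -> VolumetricImage:
    """Flip axis 0 and shift the origin so the world map is x -> 2*x_center - x."""
    flipped = np.flip(image.voxels, axis=0).copy()
    n, sx = image.shape[0], image.spacing[0]
    new_ox = 2.0 * x_center - (image.origin[0] + (n - 1) * sx)
    origin = (new_ox, image.origin[1], image.origin[2])
    return dataclasses.replace(image, voxels=flipped, origin=origin)


def reflect_sagittal(scan: PairedScan) -> PairedScan:
    """Mirror a right-leg scan about the medio-lateral grid-centre plane.

    Left-laterality scans pass through unchanged.  Voxel index ``i`` on axis 0
    maps to ``N - 1 - i``; a landmark at world ``x`` maps to ``2 x_c - x`` with
    ``x_c`` the image-centre plane of the CT grid.
    """
    if scan.laterality == "L":
        return scan
    xc = scan.ct.center_world()[0]

    def mirror(points: np.ndarray) -> np.ndarray:
        out = points.copy()
        out[:, 0] = 2.0 * xc - out[:, 0]
        return out

    return PairedScan(
        ct=_reflect_image(scan.ct, xc),
        spect=_reflect_image(scan.spect, xc),
        landmarks=scan.landmarks.map(mirror),
        laterality="L",
        timepoint=scan.timepoint,
        subject_id=scan.subject_id,
    )
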