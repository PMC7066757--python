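"""Synthetic paired CT/SPECT knee phantoms with known ground truth.

No public UKA SPECT/CT data exist, so this module renders analytic knee
phantoms that mimic the study's data regime: CT at 0.98 x 0.98 x 3 mm (or
1.27 x 1.27 x 3 mm for resolution-effect experiments), SPECT at 4.79 mm
isotropic on the same world frame, a medial tibial implant only in
post-operative scans, landmarks at analytic geometric loci, uptake hotspots,
and exactly known misalignments for recovery testing.

The bones are unions of simple solids — cylindrical shafts with cortical
shells, ellipsoidal condyles, tibial plateau and patella — embedded in a
soft-tissue cylinder over air.  Every output is a pure function of
``(spec, seed)``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .image import LandmarkSet, PairedScan, VolumetricImage
from .registration import resample_moving
from .transforms import AffineTransform, BSplineTransform, compose

__all__ = [
    "PhantomSpec",
    "GroundTruthDeformation",
    "CohortSubject",
    "generate_knee_phantom",
    "apply_ground_truth",
    "generate_cohort",
    "bone_mask_analytic",
    "analytic_bone_volume_mm3",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, intensity and noise parameters of one synthetic knee."""

    shape: tuple = (160, 160, 80)
    spacing: tuple = (0.98, 0.98, 3.0)
    spect_spacing: tuple = (4.79, 4.79, 4.79)
    # bone geometry (mm)
    femoral_shaft_radius: float = 15.0
    tibial_shaft_radius: float = 13.0
    condyle_semiaxes: tuple = (15.0, 18.0, 13.0)
    plateau_semiaxes: tuple = (26.0, 21.0, 11.0)
    patella_semiaxes: tuple = (11.0, 9.0, 12.0)
    soft_tissue_radius: float = 55.0
    cortical_fraction: float = 0.78  # interior fraction rendered as trabecular
    # intensities
    hu_air: float = -1000.0
    hu_soft: float = 40.0
    hu_trabecular: float = 300.0
    hu_cortical: float = 700.0
    hu_implant: float = 3000.0
    spect_soft: float = 20.0
    spect_bone: float = 100.0
    # ((x, y, z) mm, amplitude counts, sigma mm) Gaussian uptake hotspots
    hotspots: tuple = ()
    implant: bool = False
    # noise
    ct_noise_hu: float = 15.0
    spect_noise_scale: float = 0.1
    seed: int = 0

    def __post_init__(self):
        for name in (
            "femoral_shaft_radius",
            "tibial_shaft_radius",
            "soft_tissue_radius",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("condyle_semiaxes", "plateau_semiaxes", "patella_semiaxes"):
            if any(v <= 0 for v in getattr(self, name)):
                raise ValueError(f"{name} must be positive")
        if not (
            self.hu_soft < self.hu_trabecular < self.hu_cortical < self.hu_implant
        ):
            raise ValueError("HU levels must be ordered soft < trabecular < cortical < implant")
        ext = self.extent_mm
        for c, _, _ in self.hotspots:
            if not all(0 <= ci <= ei for ci, ei in zip(c, ext)):
                raise ValueError(f"hotspot centre {c} lies outside the grid extent {ext}")

    @property
    def extent_mm(self) -> tuple:
        return tuple(n * s for n, s in zip(self.shape, self.spacing))

    @property
    def center_xy(self) -> tuple:
        return (
            (self.shape[0] - 1) * self.spacing[0] / 2.0,
            (self.shape[1] - 1) * self.spacing[1] / 2.0,
        )

    @property
    def knee_center_z(self) -> float:
        return 0.467 * self.extent_mm[2]  # ~112 mm on the default 240 mm grid


def default_postop_hotspot(spec: PhantomSpec) -> tuple:
    """Post-operative uptake focus below the tibial insert, posterolateral."""
    cx, cy = spec.center_xy
    return ((cx + 12.0, cy + 10.0, spec.knee_center_z + 28.0), 300.0, 6.0)


# ---------------------------------------------------------------------------
# Analytic geometry


def _solids(spec: PhantomSpec):
    """Bone solids as (kind, params) tuples in world mm."""
    cx, cy = spec.center_xy
    zk = spec.knee_center_z
    zmax = spec.extent_mm[2]
    return [
        # femoral shaft: axis-z cylinder ending above the condyles
        ("cyl", (cx, cy), spec.femoral_shaft_radius, (0.0, zk - 20.0)),
        # condyles: lateral slightly smaller than medial (breaks mirror symmetry)
        ("ell", (cx - 17.0, cy, zk - 9.0), tuple(0.92 * a for a in spec.condyle_semiaxes)),
        ("ell", (cx + 18.0, cy + 2.0, zk - 8.0), spec.condyle_semiaxes),
        # patella (anterior = -y)
        ("ell", (cx, cy - 36.0, zk - 9.0), spec.patella_semiaxes),
        # tibial plateau and shaft
        ("ell", (cx, cy, zk + 20.0), spec.plateau_semiaxes),
        ("cyl", (cx + 2.0, cy), spec.tibial_shaft_radius, (zk + 28.0, zmax)),
        # fibula: small head sphere plus thin shaft
        ("ell", (cx - 28.0, cy + 6.0, zk + 38.0), (7.0, 7.0, 7.0)),
        ("cyl", (cx - 28.0, cy + 6.0), 5.0, (zk + 40.0, zmax)),
    ]


def _implant_box(spec: PhantomSpec):
    cx, cy = spec.center_xy
    zk = spec.knee_center_z
    return (
        (cx + 2.0, cy - 14.0, zk + 12.0),
        (cx + 24.0, cy + 10.0, zk + 19.0),
    )


def _solid_interior(kind, params, X, Y, Z, shrink: float = 1.0):
    if kind == "cyl":
        (cx, cy), r, (z0, z1) = params
        return ((X - cx) ** 2 + (Y - cy) ** 2 <= (shrink * r) ** 2) & (Z >= z0) & (Z <= z1)
    (cx, cy, cz), (ax, ay, az) = params
    return (
        ((X - cx) / (shrink * ax)) ** 2
        + ((Y - cy) / (shrink * ay)) ** 2
        + ((Z - cz) / (shrink * az)) ** 2
        <= 1.0
    )


def _world_grid(shape, spacing, origin=(0.0, 0.0, 0.0)):
    xs = origin[0] + np.arange(shape[0]) * spacing[0]
    ys = origin[1] + np.arange(shape[1]) * spacing[1]
    zs = origin[2] + np.arange(shape[2]) * spacing[2]
    return np.meshgrid(xs, ys, zs, indexing="ij", sparse=True)


def _bone_masks(spec: PhantomSpec, X, Y, Z):
    bone = np.zeros(np.broadcast_shapes(X.shape, Y.shape, Z.shape), dtype=bool)
    interior = np.zeros_like(bone)
    for kind, *params in _solids(spec):
        if kind == "cyl":
            p = (params[0], params[1], params[2])
        else:
            p = (params[0], params[1])
        bone |= _solid_interior(kind, p, X, Y, Z)
        interior |= _solid_interior(kind, p, X, Y, Z, shrink=spec.cortical_fraction)
    return bone, interior


def bone_mask_analytic(spec: PhantomSpec, image: VolumetricImage) -> np.ndarray:
    """Analytic bone indicator evaluated at an image's voxel centres."""
    X, Y, Z = _world_grid(image.shape, image.spacing, image.origin)
    bone, _ = _bone_masks(spec, X, Y, Z)
    return bone


def analytic_bone_volume_mm3(spec: PhantomSpec, resolution_mm: float = 0.5) -> float:
    """Bone volume by fine-grid quadrature of the analytic indicator (handles
    the overlap between solids that a per-solid closed form would not)."""
    ext = spec.extent_mm
    shape = tuple(int(np.ceil(e / resolution_mm)) for e in ext)
    X, Y, Z = _world_grid(shape, (resolution_mm,) * 3)
    bone, _ = _bone_masks(spec, X, Y, Z)
    return float(bone.sum()) * resolution_mm**3


def _landmarks(spec: PhantomSpec) -> LandmarkSet:
    cx, cy = spec.center_xy
    zk = spec.knee_center_z
    a = spec.condyle_semiaxes
    return LandmarkSet(
        {
            "FKC": (cx, cy, zk),
            "FLE": (cx - 17.0 - 0.92 * a[0], cy, zk - 9.0),
            "FME": (cx + 18.0 + a[0], cy + 2.0, zk - 8.0),
            "FTP": (cx, cy - 17.0, zk - 22.0),
            "FibulaHead": (cx - 28.0, cy + 6.0, zk + 38.0),
            "TibiaLateralPeak": (cx - 9.0, cy, zk + 20.0 - spec.plateau_semiaxes[2]),
            "TibiaMedialPeak": (cx + 9.0, cy, zk + 20.0 - spec.plateau_semiaxes[2]),
            "ProximalMargin": (cx, cy - 36.0, zk - 9.0 - spec.patella_semiaxes[2]),
            "DistalMargin": (cx, cy - 36.0, zk - 9.0 + spec.patella_semiaxes[2]),
            "LateralMargin": (cx - spec.patella_semiaxes[0], cy - 36.0, zk - 9.0),
            "MedialMargin": (cx + spec.patella_semiaxes[0], cy - 36.0, zk - 9.0),
        }
    )


# ---------------------------------------------------------------------------
# Rendering


def generate_knee_phantom(
    spec: PhantomSpec, subject_id: str = "phantom", timepoint: str | None = None
) -> PairedScan:
    """Render the paired CT + SPECT phantom described by ``spec``.

    Deterministic given ``(spec, spec.seed)``.  ``timepoint`` defaults to
    post-operative when the implant is present.
    """
    rng = np.random.default_rng(spec.seed)
    cx, cy = spec.center_xy

    # --- CT ---
    X, Y, Z = _world_grid(spec.shape, spec.spacing)
    bone, interior = _bone_masks(spec, X, Y, Z)
    soft = np.broadcast_to(
        (X - cx) ** 2 + (Y - cy) ** 2 <= spec.soft_tissue_radius**2, spec.shape
    )
    ct = np.full(spec.shape, spec.hu_air)
    ct[soft] = spec.hu_soft
    ct[bone] = spec.hu_cortical
    ct[interior] = spec.hu_trabecular
    if spec.implant:
        lo, hi = _implant_box(spec)
        box = (
            (X >= lo[0]) & (X <= hi[0]) & (Y >= lo[1]) & (Y <= hi[1])
            & (Z >= lo[2]) & (Z <= hi[2])
        )
        ct[np.broadcast_to(box, spec.shape)] = spec.hu_implant
    # partial-volume blur, then detector noise
    ct = ndimage.gaussian_filter(ct, sigma=(0.6, 0.6, 0.3))
    ct += rng.normal(0.0, spec.ct_noise_hu, size=ct.shape)
    ct_img = VolumetricImage(ct.astype(np.float32), spec.spacing, (0, 0, 0), "CT")

    # --- SPECT (same world frame, coarser grid) ---
    sshape = tuple(
        int(np.ceil(e / s)) for e, s in zip(spec.extent_mm, spec.spect_spacing)
    )
    Xs, Ys, Zs = _world_grid(sshape, spec.spect_spacing)
    sbone, _ = _bone_masks(spec, Xs, Ys, Zs)
    ssoft = np.broadcast_to(
        (Xs - cx) ** 2 + (Ys - cy) ** 2 <= spec.soft_tissue_radius**2, sshape
    )
    act = np.zeros(sshape)
    act[ssoft] = spec.spect_soft
    act[sbone] = spec.spect_bone
    for (hx, hy, hz), amp, sig in spec.hotspots:
        r2 = (Xs - hx) ** 2 + (Ys - hy) ** 2 + (Zs - hz) ** 2
        act = act + amp * np.exp(-r2 / (2.0 * sig**2))
    # collimator/reconstruction blur ~7 mm, then count-proportional noise
    act = ndimage.gaussian_filter(act, sigma=7.0 / np.asarray(spec.spect_spacing))
    act += rng.normal(0.0, 1.0, size=act.shape) * np.sqrt(
        np.clip(act, 0.0, None)
    ) * spec.spect_noise_scale
    spect_img = VolumetricImage(
        np.clip(act, 0.0, None).astype(np.float32), spec.spect_spacing, (0, 0, 0), "SPECT"
    )

    if timepoint is None:
        timepoint = "postop" if spec.implant else "preop"
    return PairedScan(
        ct=ct_img,
        spect=spect_img,
        landmarks=_landmarks(spec),
        laterality="L",
        timepoint=timepoint,
        subject_id=subject_id,
    )


# ---------------------------------------------------------------------------
# Ground-truth deformations


class _FixedPointInverse:
    """Numeric inverse of a displacement-based forward map: solve x = y - d(x)."""

    def __init__(self, forward, iterations: int = 25):
        self.forward = forward
        self.iterations = iterations

    def apply(self, points):
        y = np.atleast_2d(np.asarray(points, dtype=float))
        x = y.copy()
        for _ in range(self.iterations):
            x = y - (self.forward.apply(x) - x)
        return x if np.asarray(points).ndim > 1 else x[0]

    __call__ = apply


@dataclass
class GroundTruthDeformation:
    """Known forward world mapping with its inverse, for recovery experiments."""

    kind: str  # rigid | affine | bspline
    forward: object
    inverse: object
    parameters: dict = field(default_factory=dict)

    @classmethod
    def from_affine(cls, affine: AffineTransform, kind: str = "affine", **params):
        return cls(kind, affine, affine.inverse(), params)

    @classmethod
    def identity(cls):
        return cls.from_affine(AffineTransform.identity(), "rigid")

    @classmethod
    def random_rigid_scaling(
        cls,
        seed: int,
        center,
        max_rotation_deg: float = 10.0,
        max_translation_mm: float = 15.0,
        max_scaling: float = 0.08,
    ) -> "GroundTruthDeformation":
        """Random rotation <= max deg (per axis), translation <= max mm,
        per-axis scaling within +/- max_scaling."""
        rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
        angles = np.deg2rad(rng.uniform(-max_rotation_deg, max_rotation_deg, 3))
        trans = rng.uniform(-max_translation_mm, max_translation_mm, 3)
        scales = 1.0 + rng.uniform(-max_scaling, max_scaling, 3)
        R = _rotation_matrix(angles)
        A = R @ np.diag(scales)
        affine = AffineTransform(A, trans, np.asarray(center, dtype=float))
        kind = "rigid" if max_scaling == 0 else "affine"
        return cls.from_affine(
            affine, kind,
            angles_deg=np.rad2deg(angles).tolist(),
            translation_mm=trans.tolist(),
            scales=scales.tolist(),
        )

    @classmethod
    def smooth_bspline(
        cls, seed: int, lower, upper, grid_spacing_mm=(60.0, 60.0, 60.0),
        max_displacement_mm: float = 8.0,
    ) -> "GroundTruthDeformation":
        """Random smooth free-form warp with bounded displacement."""
        rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
        # pad the support so the fixed-point inversion can probe slightly
        # outside the nominal box without leaving the control grid
        pad = 2.0 * max_displacement_mm + 5.0
        lower = np.asarray(lower, dtype=float) - pad
        upper = np.asarray(upper, dtype=float) + pad
        b = BSplineTransform.covering(lower, upper, grid_spacing_mm)
        coeffs = rng.uniform(-1.0, 1.0, b.coefficients.shape)
        # basis weights sum to 1, so bounding the coefficients bounds the warp
        coeffs *= max_displacement_mm / np.max(np.abs(coeffs))
        fwd = BSplineTransform(b.grid_origin, b.grid_spacing, coeffs)
        return cls("bspline", fwd, _FixedPointInverse(fwd),
                   {"max_displacement_mm": max_displacement_mm})

    def verify_invertibility(self, lower, upper, n: int = 10, tol: float = 1e-3) -> float:
        """Max |forward(inverse(p)) - p| on an n^3 probe grid; raises above tol."""
        axes = [np.linspace(lo, hi, n) for lo, hi in zip(lower, upper)]
        pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
        err = float(np.max(np.abs(self.forward.apply(self.inverse.apply(pts)) - pts)))
        if err > tol:
            raise ValueError(f"forward∘inverse deviates from identity by {err:.2g} mm")
        return err


def _rotation_matrix(angles_rad) -> np.ndarray:
    ax, ay, az = angles_rad
    cx_, sx = np.cos(ax), np.sin(ax)
    cy_, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    Rx = np.array([[1, 0, 0], [0, cx_, -sx], [0, sx, cx_]])
    Ry = np.array([[cy_, 0, sy], [0, 1, 0], [-sy, 0, cy_]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def apply_ground_truth(scan: PairedScan, deformation: GroundTruthDeformation) -> PairedScan:
    """Move a scan's anatomy through a known world mapping.

    Voxels are pulled back through the deformation's inverse, so the forward
    map is exactly what a registration with this scan as moving image must
    recover; landmarks are pushed through the forward map.  Landmarks leaving
    the CT grid raise.
    """
    ct = resample_moving(scan.ct, deformation.inverse, scan.ct, "linear")
    spect = resample_moving(scan.spect, deformation.inverse, scan.spect, "linear")
    landmarks = scan.landmarks.map(deformation.forward.apply)
    hi = scan.ct.index_to_world(np.asarray(scan.ct.shape, dtype=float) - 1)
    lo = np.asarray(scan.ct.origin)
    for name in landmarks.names():
        p = landmarks[name]
        if np.any(p < lo) or np.any(p > hi):
            raise ValueError(f"landmark {name} maps outside the grid: {p}")
    return dataclasses.replace(scan, ct=ct, spect=spect, landmarks=landmarks)


# ---------------------------------------------------------------------------
# Cohorts


@dataclass
class CohortSubject:
    """One synthetic subject: pre/post scans plus every ground truth used."""

    subject_id: str
    preop: PairedScan
    postop: PairedScan
    gt_intra: GroundTruthDeformation  # post-op world -> pre-op world
    gt_anthropometry: GroundTruthDeformation  # base geometry -> subject
    is_reference: bool = False


def generate_cohort(
    n: int,
    base_spec: PhantomSpec | None = None,
    scaling_range: float = 0.10,
    shear_range: float = 0.03,
    misalign_rotation_deg: float = 5.0,
    misalign_translation_mm: float = 10.0,
    seed: int = 0,
    postop_hotspot: bool = True,
) -> list[CohortSubject]:
    """Generate ``n`` subjects with anthropometric variation and known misalignment.

    Subject 0 keeps the base geometry unchanged (identity anthropometry) and
    is flagged as the inter-subject reference.  Every other subject's
    geometry is an affine variation of the base (per-axis scaling within
    +/- ``scaling_range``, small shear).  Each pre-operative scan is the
    subject's anatomy without implant, misaligned by a random rigid motion,
    and the post-op-only uptake hotspot echoes the posterolateral tibial
    focus seen clinically.
    """
    if n < 1:
        raise ValueError("need n >= 1 subjects")
    base_spec = base_spec or PhantomSpec()
    center = np.array(
        [*base_spec.center_xy, (base_spec.shape[2] - 1) * base_spec.spacing[2] / 2.0]
    )
    subjects = []
    for i in range(n):
        sid = f"S{i:02d}"
        sseed = (int(seed) * 1009 + i * 13) & 0x7FFFFFFF
        rng = np.random.default_rng(sseed)
        if i == 0:
            S = GroundTruthDeformation.identity()
        else:
            scales = 1.0 + rng.uniform(-scaling_range, scaling_range, 3)
            M = np.diag(scales)
            M[0, 1] = rng.uniform(-shear_range, shear_range)
            M[1, 0] = rng.uniform(-shear_range, shear_range)
            S = GroundTruthDeformation.from_affine(
                AffineTransform(M, np.zeros(3), center), "affine",
                scales=scales.tolist(),
            )
        R = GroundTruthDeformation.random_rigid_scaling(
            sseed + 1,
            center,
            max_rotation_deg=misalign_rotation_deg,
            max_translation_mm=misalign_translation_mm,
            max_scaling=0.0,
        )
        hotspots = base_spec.hotspots
        if postop_hotspot:
            hotspots = hotspots + (default_postop_hotspot(base_spec),)
        post_spec = dataclasses.replace(
            base_spec, implant=True, hotspots=hotspots, seed=(sseed * 2 + 1) & 0x7FFFFFFF
        )
        pre_spec = dataclasses.replace(
            base_spec, implant=False, seed=(sseed * 2 + 2) & 0x7FFFFFFF
        )
        post_base = generate_knee_phantom(post_spec, sid, "postop")
        pre_base = generate_knee_phantom(pre_spec, sid, "preop")
        post = apply_ground_truth(post_base, S) if i else post_base
        # pre-op anatomy: subject geometry, then the rigid positioning offset
        pre_forward = GroundTruthDeformation(
            "affine", compose(S.forward, R.forward), None
        )
        pre_forward.inverse = pre_forward.forward.inverse()
        pre = apply_ground_truth(pre_base, pre_forward)
        subjects.append(
            CohortSubject(sid, pre, post, R, S, is_reference=(i == 0))
        )
    return subjects
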