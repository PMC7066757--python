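"""The registration engine.

Multimodal alignment of knee CT volumes by maximizing sampled mutual
information with Robbins-Monro adaptive stochastic gradient descent over a
smoothing-only Gaussian pyramid.  Two protocols are provided:

* **intra-subject** — affine only (12 parameters), fixed image is the
  post-operative VOI with the prosthesis masked out of the sampling region;
* **inter-subject** — affine followed by a cubic B-spline free-form
  deformation on a progressively refined control grid, with no prosthesis
  masking (every subject carries the same implant).

The default configurations are::

                       affine             non-rigid
    resolutions        3                  4
    smoothing factors  442, 221, 111      884, 442, 221, 111
    metric             NMI (16 bins)      MI (32 bins)
    optimizer          ASGD, <= 2000 it   ASGD, <= 500 it
    sampler            Halton, 2000 pts   Halton, 2000 pts
    interpolator       nearest / linear   linear / cubic B-spline
    control grid       -                  (32, 32, 16) voxels, x8 x4 x2 x1

Transforms follow the pull-back convention (fixed coordinates -> moving
coordinates), so inter- and intra-subject mappings concatenate as
``compose(inter, intra)``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import optimize
from .image import VolumetricImage, PairedScan
from .metrics import (
    ParzenJoint,
    intensity_range,
    metric_and_intensity_gradient,
    parzen_joint,
)
from .preprocess import (
    DEFAULT_BONE_LOW_HU,
    DEFAULT_MARGIN_MM,
    DEFAULT_PROSTHESIS_DILATION,
    DEFAULT_PROSTHESIS_LOW_HU,
    BoneMask,
    build_voi,
    crop,
    full_grid_mask,
    segment_bone,
)
from .sampling import sample_points
from .transforms import AffineTransform, BSplineTransform, ComposedTransform, compose

__all__ = [
    "RegistrationConfig",
    "RegistrationResult",
    "smooth_level",
    "resample_moving",
    "register_affine",
    "register_bspline",
    "register_intra",
    "register_inter",
]

_ORDER = {"nearest": 0, "linear": 1, "cubic_bspline": 3}


@dataclass
class RegistrationConfig:
    """Registration settings; the two defaults reproduce the tuned platform values."""

    mode: str = "affine"
    metric: str = "NMI"
    histogram_bins: int = 16
    smoothing_factors: tuple = ((4, 4, 2), (2, 2, 1), (1, 1, 1))
    max_iterations: int = 2000
    n_points: int = 2000
    seed: int = 0
    opt_interpolator: str = "nearest"
    final_interpolator: str = "linear"
    grid_spacing_voxels: tuple = (32, 32, 16)
    grid_multipliers: tuple = ((8, 8, 4), (4, 4, 2), (2, 2, 1), (1, 1, 1))
    asgd_a: float | None = None  # None -> auto-scaled per stage
    asgd_A: float = 50.0
    asgd_alpha: float = 0.602
    clip_percentiles: tuple = (1.0, 99.0)

    @classmethod
    def affine_defaults(cls, seed: int = 0, **overrides) -> "RegistrationConfig":
        return cls(seed=seed, **overrides)

    @classmethod
    def bspline_defaults(cls, seed: int = 0, **overrides) -> "RegistrationConfig":
        base = dict(
            mode="bspline",
            metric="MI",
            histogram_bins=32,
            smoothing_factors=((8, 8, 4), (4, 4, 2), (2, 2, 1), (1, 1, 1)),
            max_iterations=500,
            opt_interpolator="linear",
            final_interpolator="cubic_bspline",
        )
        base.update(overrides)
        return cls(seed=seed, **base)

    def __post_init__(self):
        if self.mode not in ("affine", "bspline"):
            raise ValueError(f"mode must be 'affine' or 'bspline', got {self.mode!r}")
        if self.metric not in ("NMI", "MI"):
            raise ValueError(f"metric must be 'NMI' or 'MI', got {self.metric!r}")
        if self.mode == "bspline" and len(self.grid_multipliers) < len(self.smoothing_factors):
            raise ValueError("need one control-grid multiplier per resolution stage")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RegistrationResult:
    """Outcome of one registration: the transform plus optimization telemetry."""

    transform: object
    metric_traces: list = field(default_factory=list)
    resampled: VolumetricImage | None = None
    iterations: int = 0
    final_metric: float = float("nan")
    extras: dict = field(default_factory=dict)


def smooth_level(image: VolumetricImage, factors) -> VolumetricImage:
    """Gaussian smoothing with per-axis sigma = factor / 2 voxels; no downsampling."""
    factors = np.asarray(factors, dtype=float)
    if np.any(factors < 1):
        raise ValueError(f"smoothing factors must be >= 1, got {factors}")
    sigma = factors / 2.0
    out = ndimage.gaussian_filter(np.asarray(image.voxels, dtype=float), sigma=sigma)
    return image.with_voxels(out)


def resample_moving(
    moving: VolumetricImage,
    transform,
    fixed_grid: VolumetricImage,
    interpolator: str = "linear",
) -> VolumetricImage:
    """Pull the moving image back onto the fixed grid through ``transform``."""
    order = _ORDER[interpolator]
    nx, ny, nz = fixed_grid.shape
    ii, jj, kk = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij", sparse=False
    )
    idx = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
    world = fixed_grid.index_to_world(idx)
    mapped = transform.apply(world)
    midx = moving.world_to_index(mapped)
    vals = ndimage.map_coordinates(
        np.asarray(moving.voxels, dtype=float),
        midx.T,
        order=order,
        mode="constant",
        cval=moving.background,
    )
    out = vals.reshape(fixed_grid.shape)
    return dataclasses.replace(
        moving, voxels=out, spacing=fixed_grid.spacing, origin=fixed_grid.origin
    )


# ---------------------------------------------------------------------------
# Shared per-stage machinery


def _trilinear_value_grad(vol: np.ndarray, idx: np.ndarray, spacing) -> tuple[np.ndarray, np.ndarray]:
    """Trilinear interpolation and its exact spatial derivative (per mm).

    ``idx`` are fractional voxel indices strictly inside the grid; the
    gradient is the analytic derivative of the trilinear interpolant, so a
    finite difference of the interpolated value reproduces it exactly within
    each grid cell.
    """
    n = np.asarray(vol.shape)
    i0 = np.floor(idx).astype(int)
    i0 = np.clip(i0, 0, n - 2)
    f = idx - i0
    fx, fy, fz = f[:, 0], f[:, 1], f[:, 2]
    flat = vol.ravel()
    sx, sy, sz = vol.shape[1] * vol.shape[2], vol.shape[2], 1
    base = i0[:, 0] * sx + i0[:, 1] * sy + i0[:, 2]
    c = [flat[base + a * sx + b * sy + d * sz] for a in (0, 1) for b in (0, 1) for d in (0, 1)]
    c000, c001, c010, c011, c100, c101, c110, c111 = c
    # interpolate along z, then y, then x
    a00 = c000 + (c001 - c000) * fz
    a01 = c010 + (c011 - c010) * fz
    a10 = c100 + (c101 - c100) * fz
    a11 = c110 + (c111 - c110) * fz
    b0 = a00 + (a01 - a00) * fy
    b1 = a10 + (a11 - a10) * fy
    value = b0 + (b1 - b0) * fx
    dvx = b1 - b0
    dvy = (a01 - a00) + ((a11 - a10) - (a01 - a00)) * fx
    dz00 = c001 - c000
    dz01 = c011 - c010
    dz10 = c101 - c100
    dz11 = c111 - c110
    dvz = ((dz00 + (dz01 - dz00) * fy) * (1 - fx)) + ((dz10 + (dz11 - dz10) * fy) * fx)
    grad = np.stack([dvx, dvy, dvz], axis=-1) / np.asarray(spacing)
    return value, grad


class _Stage:
    """Smoothed image pair and intensity ranges for one pyramid stage."""

    def __init__(self, fixed, moving, fixed_mask, factors, config):
        self.fixed = smooth_level(fixed, factors)
        self.moving = smooth_level(moving, factors)
        self._moving_vol = np.asarray(self.moving.voxels, dtype=float)
        self.mask = fixed_mask
        self.opt_order = _ORDER[config.opt_interpolator]
        self.fixed_range = intensity_range(
            np.asarray(self.fixed.voxels)[fixed_mask.mask], config.clip_percentiles
        )
        self.moving_range = intensity_range(
            self._moving_vol.ravel(), config.clip_percentiles
        )
        self.config = config

    def fixed_values(self, points):
        idx = self.fixed.world_to_index(points)
        return ndimage.map_coordinates(
            np.asarray(self.fixed.voxels, dtype=float),
            idx.T,
            order=self.opt_order,
            mode="constant",
            cval=self.fixed.background,
        )

    def moving_values_and_gradient(self, mapped):
        """Trilinear moving intensities, their exact spatial gradient at the
        mapped points, and the inside-extent selector.

        The optimizer always sees the trilinear interpolant of the moving
        image, whatever the configured interpolator: a nearest-neighbour
        moving value is piecewise constant in the parameters (no usable
        derivative), and mixing nearest-neighbour Parzen weights with a
        smooth spatial derivative produces a systematically biased gradient
        that drifts converged registrations off the optimum.  The configured
        optimization interpolator still governs fixed-image sampling."""
        midx = self.moving.world_to_index(mapped)
        inside = np.all((midx >= 0) & (midx <= np.asarray(self.moving.shape) - 1), axis=1)
        value, grad = _trilinear_value_grad(
            self._moving_vol, midx[inside], self.moving.spacing
        )
        return value, grad, inside

    def metric_terms(self, points, mapped):
        """(metric value, per-point dCost/dIntensity, moving gradients, inside mask).

        Cost is the negated metric; points mapping outside the moving extent
        are discarded before histogramming.
        """
        m, g, inside = self.moving_values_and_gradient(mapped)
        if not inside.any():
            raise ValueError("all sample points map outside the moving image (no overlap)")
        f = self.fixed_values(points[inside])
        pj = parzen_joint(
            f, m, self.config.histogram_bins, self.fixed_range, self.moving_range
        )
        value, dval_dm = metric_and_intensity_gradient(pj, self.config.metric)
        return value, -dval_dm, g, inside


def _auto_gain(cost_and_gradient, x, config, delta_mm, n_probe: int = 6):
    """Scale the ASGD gain so the first step moves about one voxel.

    The stochastic gradient at the stage start is probed ``n_probe`` times and
    split into its mean (the deterministic signal) and its spread (sampling
    noise).  When the signal dominates, the gain makes the first signal step
    about one voxel (``delta_mm``); as the signal-to-noise ratio drops — e.g.
    when the stage starts already converged — the gain shrinks with it, so
    pure sampling noise cannot random-walk the parameters away from the
    optimum.
    """
    if config.asgd_a is not None:
        return config.asgd_a
    grads = np.stack([cost_and_gradient(x, k)[1] for k in range(n_probe)])
    gbar = grads.mean(axis=0)
    sigma = float(np.sqrt(np.mean((grads - gbar) ** 2, axis=0).max()))
    gsig = float(np.max(np.abs(gbar)))
    # Largest |mean| expected from pure noise over K components (union bound);
    # a mean gradient below it is statistically zero -> the stage is converged
    # and the gain collapses rather than feeding noise into the parameters.
    n_params = grads.shape[1]
    threshold = 1.5 * sigma * np.sqrt(2.0 * np.log(2.0 * n_params) / n_probe)
    g_eff = max(gsig - threshold, 0.0)
    denom = max(g_eff * g_eff, sigma * sigma, 1e-24)
    return delta_mm * config.asgd_A**config.asgd_alpha * g_eff / denom


def _weighted_com(image: VolumetricImage) -> np.ndarray:
    """Intensity-weighted centre of mass.

    Weights are clipped below the median (suppresses air/soft background) and
    capped above (so a metal implant cannot dominate the estimate).  The same
    weighting is applied to fixed and moving so identical images pre-align to
    exactly zero translation.
    """
    v = np.asarray(image.voxels, dtype=float)
    w = np.clip(v - np.median(v), 0.0, 2000.0)
    if w.sum() <= 0:
        w = np.ones_like(v)
    com_idx = np.array(ndimage.center_of_mass(w))
    return image.index_to_world(com_idx)


# ---------------------------------------------------------------------------
# Affine registration


def _affine_cost_factory(stage, fixed_mask, config, center, radius, t0, stage_index):
    """Stochastic cost/gradient for the scaled 12-parameter affine model.

    Parameters are ``x[:9]/radius`` added to the identity matrix plus the
    translation ``t0 + x[9:]``, so one unit of any scaled parameter moves
    mask-boundary points by about 1 mm.  Cost is the negated metric.
    """

    def cost_and_gradient(xv, k):
        A = np.eye(3) + xv[:9].reshape(3, 3) / radius
        t = t0 + xv[9:]
        points = sample_points(
            fixed_mask, config.n_points, config.seed,
            stage_index * config.max_iterations + k,
        )
        mapped = (points - center) @ A.T + center + t
        value, d, g, inside = stage.metric_terms(points, mapped)
        rel = points[inside] - center
        gA = np.einsum("i,ia,ib->ab", d, g, rel) / radius
        gt = d @ g
        return -value, np.concatenate([gA.ravel(), gt])

    return cost_and_gradient


def register_affine(
    fixed: VolumetricImage,
    moving: VolumetricImage,
    fixed_mask: BoneMask,
    config: RegistrationConfig | None = None,
    prealign: bool = True,
) -> RegistrationResult:
    """Multiresolution affine registration driven by sampled (N)MI and ASGD.

    Each pyramid stage optimizes the 12 affine parameters from the previous
    stage's result; stage 1 starts at identity with an intensity
    centre-of-mass translation pre-alignment.  The rotation centre is the
    fixed-mask centre of mass.
    """
    config = config or RegistrationConfig.affine_defaults()
    if config.mode != "affine":
        raise ValueError(f"register_affine needs an affine config, got mode={config.mode!r}")
    if fixed_mask.voxel_count == 0 or fixed_mask.empty:
        raise ValueError("fixed mask is empty; refusing to register")

    center = fixed_mask.center_of_mass_world()
    t0 = np.zeros(3)
    if prealign:
        t0 = _weighted_com(moving) - _weighted_com(fixed)

    # Parameter scaling: one unit of any scaled parameter displaces points at
    # the mask-boundary radius by about 1 mm, making the gradient isotropic.
    imin, imax = fixed_mask.bbox_index()
    corners = fixed_mask.index_to_world(np.array([imin, imax], dtype=float))
    radius = max(float(np.max(np.abs(corners - center))), 1.0)

    def unpack(x):
        A = np.eye(3) + x[:9].reshape(3, 3) / radius
        t = t0 + x[9:]
        return A, t

    traces = []
    x = np.zeros(12)
    n_stages = len(config.smoothing_factors)
    for s, factors in enumerate(config.smoothing_factors):
        stage = _Stage(fixed, moving, fixed_mask, factors, config)
        cost_and_gradient = _affine_cost_factory(
            stage, fixed_mask, config, center, radius, t0, s
        )
        a = _auto_gain(cost_and_gradient, x, config, delta_mm=min(fixed.spacing))
        res = optimize.asgd_minimize(
            cost_and_gradient,
            x,
            config.max_iterations,
            a=a,
            A=config.asgd_A,
            alpha=config.asgd_alpha,
        )
        x = res.x
        traces.append(-res.trace)  # store the metric, not the cost

    A, t = unpack(x)
    transform = AffineTransform(A, t, center)
    resampled = resample_moving(moving, transform, fixed, config.final_interpolator)
    return RegistrationResult(
        transform=transform,
        metric_traces=traces,
        resampled=resampled,
        iterations=n_stages * config.max_iterations,
        final_metric=float(traces[-1][-1]) if config.max_iterations else float("nan"),
    )


# ---------------------------------------------------------------------------
# B-spline registration


def _control_grid_for(fixed, initial, spacing_mm) -> BSplineTransform:
    """Identity control grid covering the affine image of the fixed extent."""
    nx, ny, nz = fixed.shape
    # voxel edges (+/- half voxel), since sample points jitter within voxels
    corners_idx = np.array(
        [[i, j, k] for i in (-0.5, nx - 0.5) for j in (-0.5, ny - 0.5) for k in (-0.5, nz - 0.5)],
        dtype=float,
    )
    mapped = initial.apply(fixed.index_to_world(corners_idx))
    lo = mapped.min(axis=0) - 2.0
    hi = mapped.max(axis=0) + 2.0
    return BSplineTransform.covering(lo, hi, spacing_mm)


def register_bspline(
    fixed: VolumetricImage,
    moving: VolumetricImage,
    config: RegistrationConfig | None = None,
    initial: AffineTransform | None = None,
    fixed_mask: BoneMask | None = None,
) -> RegistrationResult:
    """Multiresolution cubic B-spline registration on top of an initial affine.

    The control-grid spacing at stage ``s`` is the base (32, 32, 16)-voxel
    spacing times the stage multiplier; finer stages are initialized by
    evaluating the coarser stage's displacement field at the new knots.
    The returned transform is ``compose(initial, bspline)``.
    """
    config = config or RegistrationConfig.bspline_defaults()
    if config.mode != "bspline":
        raise ValueError(f"register_bspline needs a bspline config, got mode={config.mode!r}")
    initial = initial if initial is not None else AffineTransform.identity()
    if fixed_mask is None:
        fixed_mask = full_grid_mask(fixed)
    if fixed_mask.voxel_count == 0 or fixed_mask.empty:
        raise ValueError("fixed mask is empty; refusing to register")

    base_mm = np.asarray(config.grid_spacing_voxels, dtype=float) * np.asarray(fixed.spacing)
    traces = []
    bspline: BSplineTransform | None = None

    for s, factors in enumerate(config.smoothing_factors):
        spacing_mm = base_mm * np.asarray(config.grid_multipliers[s], dtype=float)
        new = _control_grid_for(fixed, initial, spacing_mm)
        if bspline is not None:
            # Seed the finer grid with the coarse displacement at the new knots.
            dims = new.grid_shape
            knots = np.stack(
                np.meshgrid(*[np.arange(d) for d in dims], indexing="ij"), axis=-1
            ).reshape(-1, 3)
            kw = new.grid_origin + knots * new.grid_spacing
            prev_lo = bspline.grid_origin + bspline.grid_spacing
            prev_hi = (
                bspline.grid_origin
                + (np.asarray(bspline.grid_shape) - 2) * bspline.grid_spacing
            )
            kw_clipped = np.clip(kw, prev_lo, prev_hi)
            disp = bspline.displacement(kw_clipped)
            new = BSplineTransform(
                new.grid_origin, new.grid_spacing, disp.reshape(dims + (3,))
            )
        bspline = new
        stage = _Stage(fixed, moving, fixed_mask, factors, config)
        shape = bspline.coefficients.shape

        def cost_and_gradient(xv, k, _stage=stage, _s=s, _b=bspline, _shape=shape):
            coeffs = xv.reshape(_shape)
            b = BSplineTransform(_b.grid_origin, _b.grid_spacing, coeffs)
            points = sample_points(
                fixed_mask, config.n_points, config.seed, _s * config.max_iterations + k
            )
            q = initial.apply(points)
            idx, W = b.flat_support(q)
            flat = coeffs.reshape(-1, 3)
            mapped = q + np.einsum("nk,nkd->nd", W, flat[idx])
            value, d, g, inside = _stage.metric_terms(points, mapped)
            idx_in, W_in = idx[inside], W[inside]
            dg = d[:, None] * g  # (n_inside, 3)
            ncp = flat.shape[0]
            grad = np.stack(
                [
                    np.bincount(
                        idx_in.ravel(),
                        weights=(W_in * dg[:, ax, None]).ravel(),
                        minlength=ncp,
                    )
                    for ax in range(3)
                ],
                axis=-1,
            )
            return -value, grad.ravel()

        x = bspline.coefficients.ravel().copy()
        a = _auto_gain(cost_and_gradient, x, config, delta_mm=min(fixed.spacing))
        res = optimize.asgd_minimize(
            cost_and_gradient,
            x,
            config.max_iterations,
            a=a,
            A=config.asgd_A,
            alpha=config.asgd_alpha,
        )
        bspline = BSplineTransform(
            bspline.grid_origin, bspline.grid_spacing, res.x.reshape(shape)
        )
        traces.append(-res.trace)

    transform = compose(initial, bspline)
    resampled = resample_moving(moving, transform, fixed, config.final_interpolator)
    return RegistrationResult(
        transform=transform,
        metric_traces=traces,
        resampled=resampled,
        iterations=len(config.smoothing_factors) * config.max_iterations,
        final_metric=float(traces[-1][-1]) if config.max_iterations else float("nan"),
        extras={"bspline": bspline, "initial": initial},
    )


# ---------------------------------------------------------------------------
# Protocol drivers


def _sampling_mask_from_voi(ct_voi, prosthesis_low, dilation, bone) -> BoneMask:
    """Whole-VOI sampling mask with the dilated prosthesis carved out.

    Sample points are drawn across the full cuboidal VOI (bone and
    background alike); only metal and its streak halo are excluded.
    """
    hu = np.asarray(ct_voi.voxels)
    metal = hu >= prosthesis_low
    mask = np.ones(ct_voi.shape, dtype=bool)
    excluded = bool(metal.any())
    if excluded:
        rx, ry, rz = dilation
        structure = np.ones((2 * rx + 1, 2 * ry + 1, 2 * rz + 1), dtype=bool)
        mask &= ~ndimage.binary_dilation(metal, structure=structure)
    return BoneMask(
        mask, ct_voi.spacing, ct_voi.origin, bone=bone, prosthesis_excluded=excluded
    )


def register_intra(
    postop: PairedScan,
    preop: PairedScan,
    bone: str = "femur",
    config: RegistrationConfig | None = None,
    margin_mm=DEFAULT_MARGIN_MM,
    bone_low: float = DEFAULT_BONE_LOW_HU,
    prosthesis_low: float = DEFAULT_PROSTHESIS_LOW_HU,
) -> RegistrationResult:
    """Affine intra-subject registration: post-operative fixed, pre-operative moving.

    Both scans are cropped to the bone's landmark VOI; the sampling region is
    the post-operative VOI minus the dilated prosthesis.  The recovered
    transform applies identically to the subject's CT and SPECT (they share
    one world frame).
    """
    config = config or RegistrationConfig.affine_defaults()
    voi_fixed = build_voi(postop.landmarks, bone, postop.ct, margin_mm)
    fixed_ct = crop(postop.ct, voi_fixed)
    voi_moving = build_voi(preop.landmarks, bone, preop.ct, margin_mm)
    moving_ct = crop(preop.ct, voi_moving)

    sampling_mask = _sampling_mask_from_voi(
        fixed_ct, prosthesis_low, DEFAULT_PROSTHESIS_DILATION, bone
    )
    result = register_affine(fixed_ct, moving_ct, sampling_mask, config)
    result.extras.update(
        fixed_ct=fixed_ct,
        moving_ct=moving_ct,
        fixed_bone_mask=segment_bone(fixed_ct, bone_low, prosthesis_low, bone=bone),
        moving_bone_mask=segment_bone(moving_ct, bone_low, prosthesis_low, bone=bone),
        voi_fixed=voi_fixed,
        voi_moving=voi_moving,
    )
    return result


def register_inter(
    reference_postop: PairedScan,
    subject_postop: PairedScan,
    bone: str = "femur",
    config_affine: RegistrationConfig | None = None,
    config_bspline: RegistrationConfig | None = None,
    margin_mm=DEFAULT_MARGIN_MM,
    bone_low: float = DEFAULT_BONE_LOW_HU,
) -> RegistrationResult:
    """Inter-subject registration: affine then B-spline, no prosthesis masking.

    The fixed image is the reference subject's post-operative VOI; the same
    implant is present in every subject, so metal voxels stay in play and
    bone masks are built with an infinite prosthesis threshold.
    """
    config_affine = config_affine or RegistrationConfig.affine_defaults()
    config_bspline = config_bspline or RegistrationConfig.bspline_defaults()
    voi_fixed = build_voi(reference_postop.landmarks, bone, reference_postop.ct, margin_mm)
    fixed_ct = crop(reference_postop.ct, voi_fixed)
    voi_moving = build_voi(subject_postop.landmarks, bone, subject_postop.ct, margin_mm)
    moving_ct = crop(subject_postop.ct, voi_moving)

    sampling_mask = full_grid_mask(fixed_ct, bone=bone)
    affine_res = register_affine(fixed_ct, moving_ct, sampling_mask, config_affine)
    result = register_bspline(
        fixed_ct, moving_ct, config_bspline, initial=affine_res.transform
    )
    no_prosthesis = float("inf")
    result.metric_traces = affine_res.metric_traces + result.metric_traces
    result.extras.update(
        fixed_ct=fixed_ct,
        moving_ct=moving_ct,
        affine=affine_res.transform,
        fixed_bone_mask=segment_bone(fixed_ct, bone_low, no_prosthesis, bone=bone),
        moving_bone_mask=segment_bone(moving_ct, bone_low, no_prosthesis, bone=bone),
        voi_fixed=voi_fixed,
        voi_moving=voi_moving,
    )
    return result
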