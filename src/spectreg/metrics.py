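"""Sampled joint-histogram mutual information metrics.

The joint intensity distribution of the fixed and moving images is estimated
from a point sample with first-order (linear) Parzen windowing, which makes
the histogram — and hence MI and NMI — differentiable in the moving-image
intensities.  Entropies are measured in bits.

Two metric flavours are provided, matching their distinct roles in the
registration protocol: normalized mutual information
``NMI = (H(F) + H(M)) / H(F, M)`` for the affine stage and plain
``MI = H(F) + H(M) - H(F, M)`` for the non-rigid stage, where the larger
dynamic range introduced by the prosthesis favours the unnormalized form
with more histogram bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image import VolumetricImage

__all__ = [
    "joint_histogram",
    "mutual_information",
    "normalized_mutual_information",
    "ParzenJoint",
    "parzen_joint",
    "intensity_range",
    "interpolate",
]

_LOG2 = np.log(2.0)


def interpolate(image: VolumetricImage, world_points: np.ndarray, order: int = 1) -> np.ndarray:
    """Sample image intensities at world points (order 0 = nearest, 1 = linear)."""
    idx = image.world_to_index(world_points)
    return ndimage.map_coordinates(
        np.asarray(image.voxels, dtype=float),
        idx.T,
        order=order,
        mode="constant",
        cval=image.background,
    )


def intensity_range(values: np.ndarray, clip_percentiles=(1.0, 99.0)) -> tuple[float, float]:
    """Robust dynamic range: percentile-clipped to resist metal-streak outliers."""
    lo, hi = np.percentile(values, clip_percentiles)
    if hi <= lo:
        hi = lo + 1.0
    return float(lo), float(hi)


def _bin_positions(values: np.ndarray, vrange: tuple[float, float], bins: int):
    """Continuous bin coordinate, lower bin index and its linear weight.

    A value contributes ``1 - f`` to bin ``k0`` and ``f`` to ``k0 + 1``; at the
    range boundaries all weight collapses into the edge bin.
    """
    lo, hi = vrange
    width = (hi - lo) / bins
    t = (np.clip(values, lo, hi) - lo) / width - 0.5
    k0 = np.floor(t).astype(int)
    f = t - k0
    # Clamp edge bins: weights stay in [0, 1] and indices in [0, bins-1].
    under = k0 < 0
    over = k0 > bins - 2
    k0 = np.clip(k0, 0, bins - 2)
    f = np.where(under, 0.0, np.where(over, 1.0, f))
    interior = ~(under | over)
    return k0, f, width, interior


@dataclass
class ParzenJoint:
    """Joint histogram with the per-point bookkeeping needed for gradients."""

    joint: np.ndarray  # (bins, bins) probabilities, sums to 1
    k0: np.ndarray  # fixed lower bin per point
    kf: np.ndarray  # fixed fractional weight per point
    l0: np.ndarray  # moving lower bin per point
    lf: np.ndarray  # moving fractional weight per point
    l_interior: np.ndarray  # False where the moving value sits in a flat edge region
    moving_bin_width: float
    n: int


def parzen_joint(
    fixed_values: np.ndarray,
    moving_values: np.ndarray,
    bins: int,
    fixed_range: tuple[float, float],
    moving_range: tuple[float, float],
) -> ParzenJoint:
    """Parzen (linear) joint histogram of paired intensity samples."""
    if bins < 2:
        raise ValueError(f"need at least 2 bins, got {bins}")
    n = len(fixed_values)
    if n == 0:
        raise ValueError("no samples retained for the joint histogram (no overlap)")
    k0, kf, _, _ = _bin_positions(np.asarray(fixed_values, dtype=float), fixed_range, bins)
    l0, lf, mwidth, l_int = _bin_positions(
        np.asarray(moving_values, dtype=float), moving_range, bins
    )
    hist = np.zeros((bins, bins))
    np.add.at(hist, (k0, l0), (1 - kf) * (1 - lf))
    np.add.at(hist, (k0, l0 + 1), (1 - kf) * lf)
    np.add.at(hist, (k0 + 1, l0), kf * (1 - lf))
    np.add.at(hist, (k0 + 1, l0 + 1), kf * lf)
    return ParzenJoint(hist / n, k0, kf, l0, lf, l_int, mwidth, n)


def joint_histogram(
    fixed: VolumetricImage,
    moving: VolumetricImage,
    transform,
    points: np.ndarray,
    bins: int,
    interpolator: str = "linear",
    moving_mask=None,
    fixed_range: tuple[float, float] | None = None,
    moving_range: tuple[float, float] | None = None,
) -> np.ndarray:
    """Sampled joint probability matrix of ``fixed`` vs ``moving ∘ transform``.

    Points whose mapped position leaves the moving extent (or ``moving_mask``
    when given) are discarded; the matrix is normalized over retained points.
    """
    order = {"nearest": 0, "linear": 1}[interpolator]
    points = np.atleast_2d(np.asarray(points, dtype=float))
    mapped = transform.apply(points)
    midx = moving.world_to_index(mapped)
    inside = np.all((midx >= 0) & (midx <= np.asarray(moving.shape) - 1), axis=1)
    if moving_mask is not None:
        vi = np.rint(
            (mapped - np.asarray(moving_mask.origin)) / np.asarray(moving_mask.spacing)
        ).astype(int)
        ok = np.all((vi >= 0) & (vi < np.asarray(moving_mask.shape)), axis=1)
        sel = np.zeros(len(points), dtype=bool)
        vi_ok = vi[ok]
        sel[ok] = moving_mask.mask[vi_ok[:, 0], vi_ok[:, 1], vi_ok[:, 2]]
        inside &= sel
    if not inside.any():
        raise ValueError("all sample points map outside the moving image (no overlap)")
    f = interpolate(fixed, points[inside], order=order)
    m = interpolate(moving, mapped[inside], order=order)
    if fixed_range is None:
        fixed_range = intensity_range(f)
    if moving_range is None:
        moving_range = intensity_range(m)
    return parzen_joint(f, m, bins, fixed_range, moving_range).joint


def _entropy_bits(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)) / _LOG2)


def mutual_information(joint: np.ndarray) -> float:
    """MI = H(F) + H(M) - H(F, M) in bits; 0 log 0 := 0."""
    joint = np.asarray(joint, dtype=float)
    pf = joint.sum(axis=1)
    pm = joint.sum(axis=0)
    return _entropy_bits(pf) + _entropy_bits(pm) - _entropy_bits(joint.ravel())


def normalized_mutual_information(joint: np.ndarray) -> float:
    """NMI = (H(F) + H(M)) / H(F, M); ranges over [1, 2]."""
    joint = np.asarray(joint, dtype=float)
    hj = _entropy_bits(joint.ravel())
    if hj == 0.0:
        raise ValueError("degenerate joint histogram (single occupied cell): H(F,M) = 0")
    return (_entropy_bits(joint.sum(axis=1)) + _entropy_bits(joint.sum(axis=0))) / hj


# ---------------------------------------------------------------------------
# Derivatives with respect to the moving intensities (used by the optimizer)


def metric_and_intensity_gradient(pj: ParzenJoint, kind: str) -> tuple[float, np.ndarray]:
    """Metric value and d(metric)/d(moving intensity) per sample point.

    Moving an intensity shifts Parzen weight between its two moving bins at
    fixed fixed-bin weights, so normalization constants cancel and only the
    log terms survive.
    """
    p = pj.joint
    eps = 1e-12
    pf = p.sum(axis=1)
    pm = p.sum(axis=0)
    logp = np.log(np.maximum(p, eps))
    logpm = np.log(np.maximum(pm, eps))

    wk0 = 1 - pj.kf
    wk1 = pj.kf
    # d w_m / d m: the lower bin loses 1/width, the upper gains it; zero in
    # the flat clamped edge regions where the weights do not move.
    dwl = pj.l_interior / pj.moving_bin_width
    k0, l0 = pj.k0, pj.l0

    def joint_term(logmat):
        # sum_{k,l} w_f(k) * dw_m(l) * logmat[k, l]
        return (
            wk0 * (logmat[k0, l0 + 1] - logmat[k0, l0])
            + wk1 * (logmat[k0 + 1, l0 + 1] - logmat[k0 + 1, l0])
        ) * dwl

    scale = 1.0 / (pj.n * _LOG2)
    hj = _entropy_bits(p.ravel())
    hf = _entropy_bits(pf)
    hm = _entropy_bits(pm)
    d_hm = -scale * dwl * (logpm[l0 + 1] - logpm[l0])
    d_hj = -scale * joint_term(logp)

    if kind == "MI":
        value = hf + hm - hj
        grad = d_hm - d_hj
    elif kind == "NMI":
        if hj == 0.0:
            raise ValueError("degenerate joint histogram: H(F,M) = 0")
        value = (hf + hm) / hj
        grad = (d_hm * hj - (hf + hm) * d_hj) / (hj * hj)
    else:
        raise ValueError(f"unknown metric kind {kind!r}")
    return value, grad
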