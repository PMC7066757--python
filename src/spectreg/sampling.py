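"""Quasi-random point sampling for the stochastic similarity metric.

Each optimizer iteration draws a fresh subset of world points inside the
fixed-image mask.  Points come from the low-discrepancy Halton sequence
(bases 2, 3, 5) shifted by a per-iteration random offset (Cranley-Patterson
rotation) so consecutive iterations see different, yet well-spread, point
clouds — this smooths the stochastic cost function and avoids the grid
effect that regular sampling induces in mutual information.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.stats import qmc

from .preprocess import BoneMask

__all__ = ["sample_points"]

_MIN_ACCEPTANCE = 1e-4

# The unscrambled Halton sequence is a fixed deterministic object; cache a
# prefix of it so per-iteration calls slice instead of regenerating.
_HALTON_CACHE = np.empty((0, 3))


def _halton_base(n: int) -> np.ndarray:
    """First ``n`` points of the (2, 3, 5) Halton sequence, skipping (0,0,0)."""
    global _HALTON_CACHE
    if len(_HALTON_CACHE) < n:
        gen = qmc.Halton(d=3, scramble=False)
        gen.fast_forward(1)
        _HALTON_CACHE = gen.random(max(n, 2 * len(_HALTON_CACHE), 16384))
    return _HALTON_CACHE[:n]


def _mask_bbox_world(mask: BoneMask) -> tuple[np.ndarray, np.ndarray]:
    imin, imax = mask.bbox_index()
    lo = mask.index_to_world(imin) - 0.5 * np.asarray(mask.spacing)
    hi = mask.index_to_world(imax) + 0.5 * np.asarray(mask.spacing)
    return lo, hi


def sample_points(mask: BoneMask, n: int, seed: int, iteration: int) -> np.ndarray:
    """Draw ``n`` world points inside ``mask``, deterministic in (seed, iteration).

    Halton points on the mask's world bounding box are rotated by a random
    offset derived from ``(seed, iteration)`` and rejected against the mask,
    advancing the sequence until ``n`` survive.  Masks too small to reject
    against efficiently (< 10 n voxels) fall back to with-replacement voxel
    draws jittered within the voxel.  A mask with acceptance rate below 1e-4
    raises.
    """
    if n < 1:
        raise ValueError(f"need n >= 1 points, got {n}")
    m = mask.voxel_count
    if m == 0:
        raise ValueError("cannot sample points from an empty mask")
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, int(iteration) & 0x7FFFFFFF])
    spacing = np.asarray(mask.spacing)

    if m < 10 * n:
        warnings.warn(
            f"mask has only {m} voxels (< 10 x {n} samples); falling back to "
            "with-replacement voxel draws",
            stacklevel=2,
        )
        if not hasattr(mask, "_support_idx"):
            mask._support_idx = np.argwhere(mask.mask)
        pick = mask._support_idx[rng.integers(0, m, size=n)]
        jitter = rng.random((n, 3)) - 0.5
        return mask.index_to_world(pick + jitter)

    lo, hi = _mask_bbox_world(mask)
    offset = rng.random(3)
    accepted = []
    n_acc = 0
    n_drawn = 0
    chunk = max(4 * n, 1024)
    shape = np.asarray(mask.shape)
    while n_acc < n:
        u = (_halton_base(n_drawn + chunk)[n_drawn:] + offset) % 1.0
        pts = lo + u * (hi - lo)
        idx = np.rint((pts - np.asarray(mask.origin)) / spacing).astype(int)
        inside = np.all((idx >= 0) & (idx < shape), axis=1)
        keep = np.zeros(len(pts), dtype=bool)
        ii = idx[inside]
        keep[inside] = mask.mask[ii[:, 0], ii[:, 1], ii[:, 2]]
        sel = pts[keep]
        accepted.append(sel)
        n_acc += len(sel)
        n_drawn += chunk
        if n_drawn >= n / _MIN_ACCEPTANCE:
            raise ValueError(
                f"mask acceptance rate below {_MIN_ACCEPTANCE:g} "
                f"({n_acc}/{n_drawn} accepted); mask is degenerate"
            )
    return np.concatenate(accepted)[:n]
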