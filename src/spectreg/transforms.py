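"""Parametric spatial transforms: affine and cubic B-spline free-form deformation.

All transforms map world points (mm) to world points (mm) and follow the
pull-back convention: a registration transform maps fixed-image coordinates
into moving-image space, so the moving image can be resampled onto the fixed
grid.  Composition therefore reads ``compose(outer, inner)(p) = inner(outer(p))``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "AffineTransform",
    "BSplineTransform",
    "ComposedTransform",
    "compose",
    "transform_point",
    "save_transform",
    "load_transform",
]


@dataclass
class AffineTransform:
    """Affine world mapping ``p -> A (p - c) + c + t``.

    ``A`` is a 3x3 matrix, ``t`` a translation in mm and ``c`` an optional
    fixed rotation centre in mm.
    """

    matrix: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        if abs(np.linalg.det(self.matrix)) <= 1e-9:
            raise ValueError("affine matrix is singular (|det| <= 1e-9)")

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls()

    @classmethod
    def from_translation(cls, t) -> "AffineTransform":
        return cls(np.eye(3), np.asarray(t, dtype=float))

    def apply(self, points) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        single = p.ndim == 1
        p = np.atleast_2d(p)
        out = (p - self.center) @ self.matrix.T + self.center + self.translation
        return out[0] if single else out

    __call__ = apply

    def inverse(self) -> "AffineTransform":
        inv = np.linalg.inv(self.matrix)
        return AffineTransform(inv, -inv @ self.translation, self.center)

    def without_center(self) -> "AffineTransform":
        """Equivalent transform expressed with centre at the origin."""
        b = -self.matrix @ self.center + self.center + self.translation
        return AffineTransform(self.matrix, b, np.zeros(3))

    def to_dict(self) -> dict:
        return {
            "kind": "affine",
            "matrix": self.matrix.tolist(),
            "translation": self.translation.tolist(),
            "center": self.center.tolist(),
        }


def _bspline_weights(f: np.ndarray) -> np.ndarray:
    """Uniform cubic B-spline basis values at fractional offsets ``f`` in [0, 1].

    Returns shape ``f.shape + (4,)`` with weights for control points
    ``i-1, i, i+1, i+2``; the weights sum to 1.
    """
    f = np.asarray(f, dtype=float)
    f2 = f * f
    f3 = f2 * f
    w = np.empty(f.shape + (4,))
    w[..., 0] = (1 - 3 * f + 3 * f2 - f3) / 6.0
    w[..., 1] = (4 - 6 * f2 + 3 * f3) / 6.0
    w[..., 2] = (1 + 3 * f + 3 * f2 - 3 * f3) / 6.0
    w[..., 3] = f3 / 6.0
    return w


@dataclass
class BSplineTransform:
    """Free-form deformation ``p -> p + sum_j B_j(p) c_j`` on a uniform control grid.

    ``coefficients`` has shape ``(nx, ny, nz, 3)`` (mm displacements); the grid
    must cover the queried region plus the one-control-point support pad on
    each side that the cubic basis requires.  Zero coefficients give the
    identity mapping.
    """

    grid_origin: np.ndarray
    grid_spacing: np.ndarray
    coefficients: np.ndarray

    def __post_init__(self):
        self.grid_origin = np.asarray(self.grid_origin, dtype=float).reshape(3)
        self.grid_spacing = np.asarray(self.grid_spacing, dtype=float).reshape(3)
        if np.any(self.grid_spacing <= 0):
            raise ValueError(f"control-grid spacing must be positive, got {self.grid_spacing}")
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.ndim != 4 or self.coefficients.shape[-1] != 3:
            raise ValueError("coefficients must have shape (nx, ny, nz, 3)")
        if min(self.coefficients.shape[:3]) < 4:
            raise ValueError("control grid needs at least 4 points per axis")

    @classmethod
    def covering(cls, lower, upper, grid_spacing) -> "BSplineTransform":
        """Identity B-spline whose support covers world box [lower, upper]."""
        lower = np.asarray(lower, dtype=float)
        upper = np.asarray(upper, dtype=float)
        spacing = np.asarray(grid_spacing, dtype=float)
        n_inner = np.maximum(1, np.ceil((upper - lower) / spacing).astype(int))
        dims = n_inner + 3
        origin = lower - spacing
        return cls(origin, spacing, np.zeros(tuple(dims) + (3,)))

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.coefficients.shape[:3]

    def support_weights(self, points) -> tuple[np.ndarray, np.ndarray]:
        """Local support of each point: base control index and per-axis weights.

        Returns ``(i0, w)`` with ``i0`` of shape (N, 3) naming the first of the
        4 support control points per axis and ``w`` of shape (N, 3, 4).
        Raises if any point falls outside the padded grid support.
        """
        p = np.atleast_2d(np.asarray(points, dtype=float))
        u = (p - self.grid_origin) / self.grid_spacing
        i = np.floor(u).astype(int)
        dims = np.asarray(self.grid_shape)
        # A point with integer u on the top boundary belongs to the cell below.
        i = np.minimum(i, dims - 3)
        f = u - i
        if np.any(i < 1) or np.any(i > dims - 3) or np.any(f < -1e-9) or np.any(f > 1 + 1e-9):
            bad = np.argmax(np.any((i < 1) | (i > dims - 3), axis=1))
            raise ValueError(
                f"point {p[bad]} lies outside the B-spline control-grid support"
            )
        w = np.stack([_bspline_weights(f[:, a]) for a in range(3)], axis=1)  # (N, 3, 4)
        return i - 1, w

    def flat_support(self, points) -> tuple[np.ndarray, np.ndarray]:
        """Flattened 64-point support: (indices (N, 64) into the raveled grid,
        tensor-product weights (N, 64) summing to 1 per point)."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        i0, w = self.support_weights(p)
        offs = np.arange(4)
        nx, ny, nz = self.grid_shape
        ix = i0[:, 0, None] + offs  # (N, 4)
        iy = i0[:, 1, None] + offs
        iz = i0[:, 2, None] + offs
        idx = (
            (ix[:, :, None, None] * ny + iy[:, None, :, None]) * nz
            + iz[:, None, None, :]
        ).reshape(len(p), 64)
        W = (
            w[:, 0, :, None, None] * w[:, 1, None, :, None] * w[:, 2, None, None, :]
        ).reshape(len(p), 64)
        return idx, W

    def displacement(self, points) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=float))
        idx, W = self.flat_support(p)
        flat = self.coefficients.reshape(-1, 3)
        return np.einsum("nk,nkd->nd", W, flat[idx])

    def apply(self, points) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        single = p.ndim == 1
        p2 = np.atleast_2d(p)
        out = p2 + self.displacement(p2)
        return out[0] if single else out

    __call__ = apply

    def max_displacement(self) -> float:
        return float(np.max(np.linalg.norm(self.coefficients, axis=-1), initial=0.0))

    def to_dict(self) -> dict:
        return {
            "kind": "bspline",
            "grid_origin": self.grid_origin.tolist(),
            "grid_spacing": self.grid_spacing.tolist(),
            "grid_shape": list(self.grid_shape),
            "coefficients": self.coefficients.ravel().tolist(),
        }


@dataclass
class ComposedTransform:
    """Chain of transforms applied left to right: ``apply(p) = t_n(...t_1(p))``."""

    transforms: list

    def apply(self, points) -> np.ndarray:
        out = np.asarray(points, dtype=float)
        for t in self.transforms:
            out = t.apply(out)
        return out

    __call__ = apply

    def to_dict(self) -> dict:
        return {"kind": "composed", "transforms": [t.to_dict() for t in self.transforms]}


def compose(outer, inner):
    """Composite mapping ``p -> inner(outer(p))`` (pull-back convention).

    ``outer`` takes reference-space points into an intermediate space and
    ``inner`` continues into the final (moving) space.  Two affines collapse
    into a single :class:`AffineTransform`.
    """
    if isinstance(outer, AffineTransform) and isinstance(inner, AffineTransform):
        o = outer.without_center()
        i = inner.without_center()
        return AffineTransform(
            i.matrix @ o.matrix, i.matrix @ o.translation + i.translation, np.zeros(3)
        )
    chain = []
    for t in (outer, inner):
        chain.extend(t.transforms if isinstance(t, ComposedTransform) else [t])
    return ComposedTransform(chain)


def transform_point(transform, p) -> np.ndarray:
    """Map a single world point through a transform."""
    return transform.apply(np.asarray(p, dtype=float))


# ---------------------------------------------------------------------------
# Plain-text (JSON) serialization


def save_transform(transform, path) -> None:
    Path(path).write_text(json.dumps(transform.to_dict(), indent=1))


def _from_dict(d: dict):
    kind = d.get("kind")
    if kind == "affine":
        return AffineTransform(d["matrix"], d["translation"], d["center"])
    if kind == "bspline":
        shape = tuple(d["grid_shape"]) + (3,)
        coeffs = np.asarray(d["coefficients"], dtype=float).reshape(shape)
        return BSplineTransform(d["grid_origin"], d["grid_spacing"], coeffs)
    if kind == "composed":
        return ComposedTransform([_from_dict(t) for t in d["transforms"]])
    raise ValueError(f"unknown transform kind {kind!r}")


def load_transform(path):
    return _from_dict(json.loads(Path(path).read_text()))
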