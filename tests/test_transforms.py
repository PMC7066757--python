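"""Affine and B-spline transforms, composition and serialization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spectreg.transforms import (
    AffineTransform,
    BSplineTransform,
    ComposedTransform,
    compose,
    load_transform,
    save_transform,
    transform_point,
)


class TestAffine:
    def test_identity_leaves_points_fixed(self, rng):
        pts = rng.normal(size=(50, 3)) * 100
        assert np.allclose(AffineTransform.identity().apply(pts), pts)

    def test_inverse_round_trip(self, rng):
        A = np.eye(3) + rng.normal(scale=0.1, size=(3, 3))
        t = AffineTransform(A, rng.normal(size=3) * 10, rng.normal(size=3) * 50)
        pts = rng.normal(size=(20, 3)) * 100
        assert np.allclose(t.inverse().apply(t.apply(pts)), pts, atol=1e-9)

    def test_singular_matrix_rejected(self):
        with pytest.raises(ValueError, match="singular"):
            AffineTransform(np.zeros((3, 3)))

    def test_matches_simpleitk_affine(self, rng):
        SimpleITK = pytest.importorskip("SimpleITK")
        A = np.eye(3) + rng.normal(scale=0.05, size=(3, 3))
        t_vec = rng.normal(size=3) * 5
        c = np.array([10.0, -5.0, 20.0])
        ours = AffineTransform(A, t_vec, c)
        theirs = SimpleITK.AffineTransform(3)
        theirs.SetMatrix(A.ravel())
        theirs.SetTranslation(t_vec)
        theirs.SetCenter(c)
        for p in rng.normal(size=(10, 3)) * 50:
            assert np.allclose(ours.apply(p), theirs.TransformPoint(p), atol=1e-9)


class TestCompose:
    def test_identity_neutral(self, rng):
        T = AffineTransform(np.diag([1.1, 0.9, 1.0]), [1, 2, 3])
        I = AffineTransform.identity()
        pts = rng.normal(size=(20, 3)) * 40
        assert np.allclose(compose(I, T).apply(pts), T.apply(pts))
        assert np.allclose(compose(T, I).apply(pts), T.apply(pts))

    def test_translations_add(self):
        a = AffineTransform.from_translation([1, 2, 3])
        b = AffineTransform.from_translation([10, -2, 0.5])
        c = compose(a, b)
        assert np.allclose(c.apply([0, 0, 0]), [11, 0, 3.5])

    def test_affine_composition_equals_pointwise(self, rng):
        for _ in range(5):
            a = AffineTransform(
                np.eye(3) + rng.normal(scale=0.1, size=(3, 3)),
                rng.normal(size=3) * 10,
                rng.normal(size=3) * 20,
            )
            b = AffineTransform(
                np.eye(3) + rng.normal(scale=0.1, size=(3, 3)),
                rng.normal(size=3) * 10,
            )
            comp = compose(a, b)
            assert isinstance(comp, AffineTransform)
            pts = rng.normal(size=(100, 3)) * 80
            assert np.allclose(comp.apply(pts), b.apply(a.apply(pts)), atol=1e-9)

    def test_affine_bspline_chain_applies_in_order(self):
        b = BSplineTransform.covering((0, 0, 0), (40, 40, 40), (10, 10, 10))
        a = AffineTransform.from_translation([5, 0, 0])
        chain = compose(a, b)
        assert isinstance(chain, ComposedTransform)
        p = np.array([12.0, 20.0, 20.0])
        assert np.allclose(chain.apply(p), p + [5, 0, 0])  # zero-coefficient b-spline


class TestBSpline:
    def test_zero_coefficients_is_identity(self, rng):
        b = BSplineTransform.covering((0, 0, 0), (50, 60, 70), (12, 15, 20))
        pts = rng.uniform([0, 0, 0], [50, 60, 70], size=(200, 3))
        assert np.allclose(b.apply(pts), pts)

    def test_central_weight_of_displaced_control_point(self):
        """Displacing one knot by d moves the knot's own location by d*(2/3)^3."""
        b = BSplineTransform.covering((0, 0, 0), (40, 40, 40), (10, 10, 10))
        coeffs = b.coefficients.copy()
        coeffs[3, 3, 3] = (7.0, -4.0, 2.0)
        b = BSplineTransform(b.grid_origin, b.grid_spacing, coeffs)
        knot_world = b.grid_origin + 3 * b.grid_spacing
        disp = b.apply(knot_world) - knot_world
        assert np.allclose(disp, np.array([7.0, -4.0, 2.0]) * (2.0 / 3.0) ** 3)

    def test_weights_partition_unity(self, rng):
        b = BSplineTransform.covering((0, 0, 0), (30, 30, 30), (8, 9, 10))
        pts = rng.uniform(0, 30, size=(100, 3))
        _, W = b.flat_support(pts)
        assert np.allclose(W.sum(axis=1), 1.0)

    def test_point_outside_support_raises(self):
        b = BSplineTransform.covering((0, 0, 0), (30, 30, 30), (10, 10, 10))
        with pytest.raises(ValueError, match="support"):
            transform_point(b, (-25.0, 10.0, 10.0))

    def test_matches_simpleitk_bspline_displacement(self, rng):
        SimpleITK = pytest.importorskip("SimpleITK")
        ours = BSplineTransform.covering((0, 0, 0), (40, 40, 40), (10, 10, 10))
        coeffs = rng.normal(scale=3.0, size=ours.coefficients.shape)
        ours = BSplineTransform(ours.grid_origin, ours.grid_spacing, coeffs)
        theirs = SimpleITK.BSplineTransform(3, 3)
        nx, ny, nz = ours.grid_shape
        theirs.SetTransformDomainOrigin(tuple(ours.grid_origin + ours.grid_spacing))
        theirs.SetTransformDomainDirection((1, 0, 0, 0, 1, 0, 0, 0, 1))
        theirs.SetTransformDomainMeshSize((nx - 3, ny - 3, nz - 3))
        theirs.SetTransformDomainPhysicalDimensions(
            tuple(ours.grid_spacing * np.array([nx - 3, ny - 3, nz - 3]))
        )
        # SimpleITK stores one flattened (z-fastest... actually x-fastest) array per axis
        params = np.concatenate(
            [coeffs[..., d].transpose(2, 1, 0).ravel() for d in range(3)]
        )
        theirs.SetParameters(params)
        pts = rng.uniform(5, 35, size=(25, 3))
        for p in pts:
            assert np.allclose(ours.apply(p), theirs.TransformPoint(p), atol=1e-8)


class TestSerialization:
    @settings(max_examples=10, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 1000))
    def test_affine_round_trip(self, tmp_path_factory, seed):
        rng = np.random.default_rng(seed)
        t = AffineTransform(
            np.eye(3) + rng.normal(scale=0.1, size=(3, 3)),
            rng.normal(size=3),
            rng.normal(size=3),
        )
        path = tmp_path_factory.mktemp("t") / "t.json"
        save_transform(t, path)
        back = load_transform(path)
        pts = rng.normal(size=(10, 3)) * 30
        assert np.allclose(back.apply(pts), t.apply(pts))

    def test_composed_chain_round_trip(self, tmp_path, rng):
        b = BSplineTransform.covering((0, 0, 0), (30, 30, 30), (10, 10, 10))
        coeffs = rng.normal(scale=2.0, size=b.coefficients.shape)
        b = BSplineTransform(b.grid_origin, b.grid_spacing, coeffs)
        chain = compose(AffineTransform.from_translation([1, 2, 3]), b)
        save_transform(chain, tmp_path / "c.json")
        back = load_transform(tmp_path / "c.json")
        pts = rng.uniform(8, 22, size=(20, 3))
        assert np.allclose(back.apply(pts), chain.apply(pts))
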