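"""Registration engine: pyramid, resampling, gradients, recovery."""

import dataclasses

import numpy as np
import pytest
from scipy import ndimage

from spectreg.image import VolumetricImage
from spectreg.phantom import (
    GroundTruthDeformation,
    apply_ground_truth,
    generate_knee_phantom,
)
from spectreg.preprocess import full_grid_mask
from spectreg.registration import (
    RegistrationConfig,
    _affine_cost_factory,
    _Stage,
    register_affine,
    register_bspline,
    register_intra,
    resample_moving,
    smooth_level,
)
from spectreg.transforms import AffineTransform


class TestConfigDefaults:
    def test_affine_defaults_reproduce_tuned_values(self):
        cfg = RegistrationConfig.affine_defaults()
        assert cfg.metric == "NMI" and cfg.histogram_bins == 16
        assert cfg.smoothing_factors == ((4, 4, 2), (2, 2, 1), (1, 1, 1))
        assert cfg.max_iterations == 2000 and cfg.n_points == 2000
        assert cfg.opt_interpolator == "nearest" and cfg.final_interpolator == "linear"

    def test_bspline_defaults_reproduce_tuned_values(self):
        cfg = RegistrationConfig.bspline_defaults()
        assert cfg.metric == "MI" and cfg.histogram_bins == 32
        assert cfg.smoothing_factors == ((8, 8, 4), (4, 4, 2), (2, 2, 1), (1, 1, 1))
        assert cfg.max_iterations == 500
        assert cfg.grid_spacing_voxels == (32, 32, 16)
        assert cfg.grid_multipliers == ((8, 8, 4), (4, 4, 2), (2, 2, 1), (1, 1, 1))
        assert cfg.final_interpolator == "cubic_bspline"

    def test_stage_one_nonrigid_control_spacing_in_voxels(self):
        cfg = RegistrationConfig.bspline_defaults()
        spacing = np.asarray(cfg.grid_spacing_voxels) * np.asarray(cfg.grid_multipliers[0])
        np.testing.assert_array_equal(spacing, (256, 256, 64))


class TestSmoothLevel:
    def test_constant_image_unchanged(self):
        img = VolumetricImage(np.full((16, 16, 16), 3.0), (1, 1, 1))
        out = smooth_level(img, (4, 4, 2))
        assert np.allclose(out.voxels, 3.0)
        assert out.shape == img.shape  # smoothing-only pyramid, no downsampling

    def test_impulse_second_moment_matches_sigma(self):
        """Factors (4, 4, 2) mean sigma (2, 2, 1) voxels; check via moments."""
        img = np.zeros((33, 33, 33))
        img[16, 16, 16] = 1.0
        out = smooth_level(VolumetricImage(img, (1, 1, 1)), (4, 4, 2)).voxels
        coords = np.arange(33) - 16.0
        for axis, sigma in zip(range(3), (2.0, 2.0, 1.0)):
            marg = out.sum(axis=tuple(a for a in range(3) if a != axis))
            var = np.sum(marg * coords**2) / marg.sum()
            assert abs(var - sigma**2) / sigma**2 < 0.05

    def test_factors_below_one_rejected(self):
        with pytest.raises(ValueError, match=">= 1"):
            smooth_level(VolumetricImage(np.zeros((4, 4, 4)), (1, 1, 1)), (0.5, 1, 1))


class TestResampleMoving:
    def test_identity_same_grid_nearest_is_exact(self, rng):
        img = VolumetricImage(rng.normal(size=(12, 10, 8)), (1, 1.5, 2))
        out = resample_moving(img, AffineTransform.identity(), img, "nearest")
        np.testing.assert_array_equal(out.voxels, img.voxels)

    def test_one_voxel_translation_equals_index_shift(self, rng):
        img = VolumetricImage(rng.normal(size=(12, 10, 8)), (1.0, 1.5, 2.0))
        # pull-back: moving value at fixed point p is moving(p + spacing_x)
        t = AffineTransform.from_translation([1.0, 0, 0])
        out = resample_moving(img, t, img, "nearest")
        np.testing.assert_allclose(out.voxels[:-1], img.voxels[1:])


class TestGradientOracle:
    def test_analytic_gradient_matches_central_differences(self, rng):
        """ASGD's analytic metric gradient vs finite differences, 16^3 fixed grid.

        The moving volume is padded so no sample crosses the image boundary
        (where discarding a point makes the sampled metric discontinuous).
        """
        f = ndimage.gaussian_filter(rng.normal(size=(16, 16, 16)), 2.0) * 100
        m = ndimage.gaussian_filter(rng.normal(size=(32, 32, 32)), 2.0) * 100
        fixed = VolumetricImage(f, (1, 1, 1), origin=(8, 8, 8))
        moving = VolumetricImage(m, (1, 1, 1))
        mask = full_grid_mask(fixed)
        cfg = RegistrationConfig.affine_defaults(
            seed=3, opt_interpolator="linear", n_points=2000
        )
        with pytest.warns(UserWarning, match="with-replacement"):
            stage = _Stage(fixed, moving, mask, (1, 1, 1), cfg)
            cost = _affine_cost_factory(
                stage, mask, cfg, mask.center_of_mass_world(), 8.0, np.zeros(3), 0
            )
            h = 1e-7
            for trial in range(20):
                x = rng.normal(0, 0.5, 12)
                _, g = cost(x, trial)
                fd = np.empty(12)
                for j in range(12):
                    e = np.zeros(12)
                    e[j] = h
                    fd[j] = (cost(x + e, trial)[0] - cost(x - e, trial)[0]) / (2 * h)
                rel = np.linalg.norm(fd - g) / np.linalg.norm(fd)
                assert rel < 1e-4


class TestAffineRecovery:
    def test_self_registration_stays_at_identity(self, small_postop_phantom):
        # needs the full gain-annealing schedule to settle below half a voxel
        cfg = RegistrationConfig.affine_defaults(seed=0, max_iterations=800)
        res = register_intra(
            small_postop_phantom,
            dataclasses.replace(small_postop_phantom, timepoint="preop"),
            "femur",
            cfg,
        )
        fixed = res.extras["fixed_ct"]
        corners = fixed.index_to_world(
            np.array([[0, 0, 0], list(np.asarray(fixed.shape) - 1)], dtype=float)
        )
        err = np.abs(res.transform.apply(corners) - corners)
        assert np.all(err < 0.5 * np.asarray(fixed.spacing))

    def test_known_translation_recovered_within_one_voxel(
        self, small_spec, small_phantom, small_postop_phantom, quick_affine_config
    ):
        gt = GroundTruthDeformation.from_affine(
            AffineTransform.from_translation([10.0, 5.0, 6.0]), "rigid"
        )
        pre = apply_ground_truth(small_phantom, gt)
        res = register_intra(small_postop_phantom, pre, "femur", quick_affine_config)
        pts = small_postop_phantom.landmarks.as_array(["FKC", "FLE", "FME", "FTP"])
        err = np.abs(res.transform.apply(pts) - gt.forward.apply(pts))
        assert np.all(err < np.asarray(small_phantom.ct.spacing))

    def test_metric_trace_improves_per_stage(
        self, small_phantom, small_postop_phantom, quick_affine_config
    ):
        gt = GroundTruthDeformation.from_affine(
            AffineTransform.from_translation([8.0, -4.0, 5.0]), "rigid"
        )
        pre = apply_ground_truth(small_phantom, gt)
        res = register_intra(small_postop_phantom, pre, "femur", quick_affine_config)
        gains = [np.median(tr[-20:]) - np.median(tr[:20]) for tr in res.metric_traces]
        assert np.median(gains) >= 0  # metric does not degrade within stages

    def test_determinism_bitwise(self, small_phantom, small_postop_phantom, quick_affine_config):
        gt = GroundTruthDeformation.from_affine(
            AffineTransform.from_translation([6.0, 3.0, -4.0]), "rigid"
        )
        pre = apply_ground_truth(small_phantom, gt)
        r1 = register_intra(small_postop_phantom, pre, "femur", quick_affine_config)
        r2 = register_intra(small_postop_phantom, pre, "femur", quick_affine_config)
        np.testing.assert_array_equal(r1.transform.matrix, r2.transform.matrix)
        np.testing.assert_array_equal(r1.transform.translation, r2.transform.translation)

    def test_empty_mask_refused(self, small_phantom, quick_affine_config):
        from spectreg.preprocess import BoneMask

        empty = BoneMask(
            np.zeros(small_phantom.ct.shape, dtype=bool),
            small_phantom.ct.spacing,
            small_phantom.ct.origin,
        )
        with pytest.raises(ValueError, match="empty"):
            register_affine(small_phantom.ct, small_phantom.ct, empty, quick_affine_config)


class TestBsplineRecovery:
    def test_self_registration_keeps_displacement_below_half_voxel(
        self, small_postop_phantom, quick_bspline_config
    ):
        from spectreg.preprocess import build_voi, crop

        voi = build_voi(small_postop_phantom.landmarks, "femur", small_postop_phantom.ct)
        fixed = crop(small_postop_phantom.ct, voi)
        res = register_bspline(fixed, fixed, quick_bspline_config)
        max_disp = res.extras["bspline"].max_displacement()
        assert max_disp < 0.5 * min(fixed.spacing)

    def test_smooth_warp_reduces_landmark_error(
        self, small_spec, small_postop_phantom, quick_bspline_config, quick_affine_config
    ):
        """A known smooth warp (<= 8 mm) is substantially recovered."""
        from spectreg.registration import register_inter

        gt = GroundTruthDeformation.smooth_bspline(
            3, (0, 0, 0), small_postop_phantom.ct.extent_mm,
            grid_spacing_mm=(80, 80, 80), max_displacement_mm=8.0,
        )
        warped = apply_ground_truth(small_postop_phantom, gt)
        res = register_inter(
            small_postop_phantom, warped, "femur",
            quick_affine_config, quick_bspline_config,
        )
        pts = small_postop_phantom.landmarks.as_array(["FKC", "FLE", "FME", "FTP"])
        before = np.abs(gt.forward.apply(pts) - pts)
        after = np.abs(res.transform.apply(pts) - gt.forward.apply(pts))
        # mean in-plane landmark error within 2 voxels and improved vs identity
        assert after[:, :2].mean() < 2 * small_postop_phantom.ct.spacing[0]
        assert after.mean() < before.mean()
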