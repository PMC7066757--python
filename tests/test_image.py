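"""Image data model, NIfTI/DICOM I/O, resampling and laterality reflection."""

import numpy as np
import pytest

from spectreg.image import (
    PairedScan,
    VolumetricImage,
    read_image,
    read_landmarks,
    read_paired_scan,
    reflect_sagittal,
    resample,
    resampled_shape,
    write_image,
    write_landmarks,
)


def _image(shape=(8, 6, 4), spacing=(0.98, 0.98, 3.0), origin=(0, 0, 0), seed=0):
    rng = np.random.default_rng(seed)
    return VolumetricImage(
        rng.integers(-1000, 2000, size=shape).astype(np.float32), spacing, origin, "CT"
    )


class TestVolumetricImage:
    def test_world_index_round_trip_is_exact(self):
        img = _image(origin=(-250.0, -250.0, 0.0))
        idx = np.array([[0, 0, 0], [7, 5, 3], [2, 4, 1]], dtype=float)
        assert np.allclose(img.world_to_index(img.index_to_world(idx)), idx)

    def test_world_of_voxel_is_origin_plus_index_times_spacing(self):
        img = _image(spacing=(1.27, 1.27, 3.0), origin=(5.0, -3.0, 10.0))
        assert np.allclose(img.index_to_world([2, 1, 3]), [5 + 2 * 1.27, -3 + 1.27, 19.0])

    @pytest.mark.parametrize("bad", [(0, 1, 1), (-1, 1, 1)])
    def test_nonpositive_spacing_rejected(self, bad):
        with pytest.raises(ValueError, match="spacing"):
            VolumetricImage(np.zeros((2, 2, 2)), bad)


class TestNiftiRoundTrip:
    @pytest.mark.parametrize(
        "spacing,origin",
        [
            ((0.98, 0.98, 3.0), (0.0, 0.0, 0.0)),
            ((1.27, 1.27, 3.0), (0.0, 0.0, 0.0)),
            ((4.79, 4.79, 4.79), (-250.0, -250.0, 0.0)),
        ],
    )
    def test_voxels_spacing_origin_survive(self, tmp_path, spacing, origin):
        img = _image(spacing=spacing, origin=origin)
        path = tmp_path / "vol.nii.gz"
        write_image(img, path)
        back = read_image(path)
        np.testing.assert_array_equal(back.voxels, img.voxels)
        assert np.allclose(back.spacing, spacing, atol=1e-6)
        assert np.allclose(back.origin, origin, atol=1e-6)

    def test_constant_zero_image_round_trips(self, tmp_path):
        img = VolumetricImage(np.zeros((4, 4, 4)), (1, 1, 1))
        write_image(img, tmp_path / "z.nii")
        assert np.all(read_image(tmp_path / "z.nii").voxels == 0)


def _write_dicom_series(directory, n_slices=4, spacing=(0.8, 0.8, 2.5), bad_slice=None):
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    directory.mkdir(exist_ok=True)
    series_uid = generate_uid()
    for k in range(n_slices):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
        ds.Modality = "CT"
        ds.SeriesInstanceUID = series_uid
        ds.Rows = 6
        ds.Columns = 5
        ps = list(spacing[:2]) if bad_slice != k else [spacing[0] * 2, spacing[1]]
        ds.PixelSpacing = [str(ps[1]), str(ps[0])]  # row spacing (y), col spacing (x)
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.ImagePositionPatient = [0.0, 0.0, k * spacing[2]]
        ds.SliceThickness = spacing[2]
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = -1024.0
        arr = (np.arange(30, dtype=np.int16) + 1024 + 100 * k).reshape(6, 5)
        ds.PixelData = arr.tobytes()
        ds.save_as(str(directory / f"slice{k:03d}.dcm"), enforce_file_format=True)


class TestDicom:
    def test_series_spacing_and_hu_rescale(self, tmp_path):
        d = tmp_path / "series"
        _write_dicom_series(d)
        img = read_image(d)
        assert img.modality == "CT"
        assert np.allclose(img.spacing, (0.8, 0.8, 2.5))
        # first slice, row 0 col 0: raw 1024 -> HU 0 after rescale
        assert img.voxels[0, 0, 0] == 0
        # slice k adds 100 raw counts -> +100 HU
        assert img.voxels[0, 0, 1] == 100

    def test_mixed_pixel_spacing_names_offending_file(self, tmp_path):
        d = tmp_path / "series"
        _write_dicom_series(d, bad_slice=2)
        with pytest.raises(ValueError, match="slice002"):
            read_image(d)


class TestLandmarks:
    def test_round_trip(self, tmp_path, small_phantom):
        path = tmp_path / "lm.txt"
        write_landmarks(small_phantom.landmarks, path)
        back = read_landmarks(path)
        assert set(back.names()) == set(small_phantom.landmarks.names())
        for n in back.names():
            assert np.allclose(back[n], small_phantom.landmarks[n], atol=1e-5)

    def test_unknown_name_lists_valid_names(self, tmp_path):
        path = tmp_path / "lm.txt"
        path.write_text("FHC 1 2 3\n")
        with pytest.raises(ValueError, match="FHC.*FKC"):
            read_landmarks(path)


class TestReadPairedScan:
    def test_round_trip_preserves_headers(self, tmp_path, small_phantom):
        write_image(small_phantom.ct, tmp_path / "ct.nii.gz")
        write_image(small_phantom.spect, tmp_path / "spect.nii.gz")
        write_landmarks(small_phantom.landmarks, tmp_path / "lm.txt")
        scan = read_paired_scan(
            tmp_path / "ct.nii.gz", tmp_path / "spect.nii.gz", tmp_path / "lm.txt"
        )
        np.testing.assert_array_equal(scan.ct.voxels, small_phantom.ct.voxels)
        assert np.allclose(scan.ct.spacing, small_phantom.ct.spacing, atol=1e-6)
        assert scan.spect.modality == "SPECT"


class TestResample:
    def test_extent_preserving_dimensions_for_spect_grid(self):
        # hand computation: ceil(128*4.79/0.98) = 626 in-plane, ceil(128*4.79/3) = 205
        assert resampled_shape((128, 128, 128), (4.79,) * 3, (0.98, 0.98, 3.0)) == (
            626,
            626,
            205,
        )

    def test_identity_spacing_nearest_is_identity(self):
        img = _image()
        out = resample(img, img.spacing, "nearest")
        np.testing.assert_array_equal(out.voxels, img.voxels)

    @pytest.mark.parametrize("interp", ["nearest", "linear", "cubic_bspline"])
    def test_constant_image_stays_constant_inside_extent(self, interp):
        img = VolumetricImage(np.full((12, 12, 12), 7.0), (2, 2, 2))
        out = resample(img, (1.5, 1.5, 1.5), interp)
        interior = out.voxels[2:-3, 2:-3, 2:-3]
        assert np.allclose(interior, 7.0, atol=1e-6)

    def test_round_trip_mae_below_one_percent_of_range(self):
        x, y, z = np.mgrid[0:24, 0:24, 0:24]
        smooth = 100 * np.exp(-((x - 12) ** 2 + (y - 12) ** 2 + (z - 12) ** 2) / 60.0)
        img = VolumetricImage(smooth, (1, 1, 1))
        down = resample(img, (1.5, 1.5, 1.5), "linear")
        back = resample(down, (1, 1, 1), "linear")
        core = (slice(2, 22),) * 3
        mae = np.mean(np.abs(back.voxels[core] - smooth[core]))
        assert mae < 0.01 * np.ptp(smooth)

    def test_matches_simpleitk_linear_resampling(self):
        SimpleITK = pytest.importorskip("SimpleITK")
        img = _image(shape=(10, 9, 8), spacing=(1.0, 1.5, 2.0), seed=3)
        ours = resample(img, (0.7, 0.7, 0.9), "linear")
        sitk_img = SimpleITK.GetImageFromArray(
            np.ascontiguousarray(img.voxels.astype(float).transpose(2, 1, 0))
        )
        sitk_img.SetSpacing(img.spacing)
        res = SimpleITK.Resample(
            sitk_img,
            ours.shape,
            SimpleITK.Transform(),
            SimpleITK.sitkLinear,
            (0.0, 0.0, 0.0),
            (0.7, 0.7, 0.9),
            (1.0, 0.0, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0, 1.0),
            float(img.background),
        )
        theirs = SimpleITK.GetArrayFromImage(res).transpose(2, 1, 0)
        # interiors agree; border handling of out-of-extent samples may differ
        core = (slice(1, -2),) * 3
        assert np.allclose(ours.voxels[core], theirs[core], atol=1e-3)


class TestReflectSagittal:
    def test_left_scan_is_untouched(self, small_phantom):
        assert reflect_sagittal(small_phantom) is small_phantom

    def _as_right(self, scan):
        import dataclasses

        return dataclasses.replace(scan, laterality="R")

    def test_involution_restores_voxels_and_landmarks(self, small_phantom):
        right = self._as_right(small_phantom)
        once = reflect_sagittal(right)
        twice = reflect_sagittal(self._as_right(once))
        np.testing.assert_array_equal(twice.ct.voxels, right.ct.voxels)
        np.testing.assert_array_equal(twice.spect.voxels, right.spect.voxels)
        for n in right.landmarks.names():
            assert np.allclose(twice.landmarks[n], right.landmarks[n], atol=1e-9)

    def test_histogram_preserved_and_mirror_formulas(self, small_phantom):
        right = self._as_right(small_phantom)
        out = reflect_sagittal(right)
        assert out.laterality == "L"
        # voxel multiset unchanged
        np.testing.assert_array_equal(
            np.sort(out.ct.voxels, axis=0), np.sort(right.ct.voxels, axis=0)
        )
        # index i -> N-1-i on axis 0
        np.testing.assert_array_equal(out.ct.voxels, right.ct.voxels[::-1])
        # landmark x -> 2*x_center - x
        xc = right.ct.center_world()[0]
        for n in right.landmarks.names():
            assert np.isclose(out.landmarks[n][0], 2 * xc - right.landmarks[n][0])

    def test_mirrored_landmark_sits_on_mirrored_intensity_feature(self, small_phantom):
        """The mirrored FLE must sample the same CT intensity the original did."""
        right = self._as_right(small_phantom)
        out = reflect_sagittal(right)
        from spectreg.metrics import interpolate

        orig = interpolate(right.ct, right.landmarks["FLE"][None], order=1)
        mirr = interpolate(out.ct, out.landmarks["FLE"][None], order=1)
        assert abs(orig - mirr) < 40  # same tissue class despite interpolation/noise
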