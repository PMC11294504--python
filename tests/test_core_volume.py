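import numpy as np
import pytest

from cardioreorient.core_volume import (
    BoundingBox,
    Volume3D,
    crop_volume,
    read_volume,
    resample_volume,
    write_volume,
)


def make_vol(shape=(8, 8, 8), value=3.0, spacing=(1.0, 1.0, 1.0)):
    return Volume3D(np.full(shape, value), spacing)


class TestVolumeModel:
    def test_rejects_invalid_geometry(self):
        with pytest.raises(ValueError):
            Volume3D(np.zeros((4, 4)), (1, 1, 1))
        with pytest.raises(ValueError):
            Volume3D(np.zeros((4, 4, 1)), (1, 1, 1))
        with pytest.raises(ValueError):
            Volume3D(np.zeros((4, 4, 4)), (1, -1, 1))
        with pytest.raises(ValueError):
            Volume3D(np.full((4, 4, 4), -1.0), (1, 1, 1))
        with pytest.raises(ValueError):
            Volume3D(np.full((4, 4, 4), np.nan), (1, 1, 1))

    def test_bounding_box_validation(self):
        with pytest.raises(ValueError):
            BoundingBox((0, 0, 0), (0, 4, 4))
        with pytest.raises(ValueError):
            BoundingBox((-1, 0, 0), (4, 4, 4))
        assert BoundingBox((1, 2, 3), (4, 5, 6)).extents == (3, 3, 3)


class TestNiftiRoundtrip:
    def test_write_read_identity(self, tmp_path):
        rng = np.random.default_rng(0)
        vol = Volume3D(rng.uniform(0, 10, (8, 8, 8)), (2.0, 2.0, 3.0), (1.0, -2.0, 5.0))
        path = tmp_path / "vol.nii.gz"
        write_volume(vol, path)
        back = read_volume(path)
        np.testing.assert_allclose(back.data, vol.data, rtol=1e-6)
        np.testing.assert_allclose(back.spacing, vol.spacing)
        np.testing.assert_allclose(back.origin, vol.origin)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_volume(tmp_path / "nope.nii")


class TestDicomSeries:
    def _write_series(self, tmp_path, nz=5, rows=8, cols=8, shuffle=True, rows_per_slice=None):
        from pydicom.dataset import Dataset, FileMetaDataset
        from pydicom.uid import ExplicitVRLittleEndian, generate_uid

        tmp_path.mkdir(parents=True, exist_ok=True)
        order = np.random.default_rng(1).permutation(nz) if shuffle else np.arange(nz)
        for i, z in enumerate(order):
            rows = rows_per_slice[i] if rows_per_slice else rows
            ds = Dataset()
            ds.file_meta = FileMetaDataset()
            ds.file_meta.TransferSyntaxUID = ExplicitVRLittleEndian
            ds.file_meta.MediaStorageSOPClassUID = generate_uid()
            ds.file_meta.MediaStorageSOPInstanceUID = generate_uid()
            ds.SOPClassUID = ds.file_meta.MediaStorageSOPClassUID
            ds.SOPInstanceUID = ds.file_meta.MediaStorageSOPInstanceUID
            ds.Rows, ds.Columns = rows, cols
            ds.PixelSpacing = [2.0, 2.0]
            ds.ImagePositionPatient = [0.0, 0.0, float(z) * 3.0]
            ds.SliceThickness = 3.0
            ds.SamplesPerPixel = 1
            ds.PhotometricInterpretation = "MONOCHROME2"
            ds.BitsAllocated = 16
            ds.BitsStored = 16
            ds.HighBit = 15
            ds.PixelRepresentation = 0
            arr = np.full((int(rows), cols), int(z), dtype=np.uint16)
            ds.PixelData = arr.tobytes()
            ds.save_as(tmp_path / f"slice{i}.dcm", enforce_file_format=True)
        return tmp_path

    def test_shuffled_slices_sorted_by_position(self, tmp_path):
        d = self._write_series(tmp_path)
        vol = read_volume(d, format="dicom_dir")
        assert vol.shape == (8, 8, 5)
        # slice value equals its z index once sorted by position
        for z in range(5):
            assert np.all(vol.data[:, :, z] == z)
        np.testing.assert_allclose(vol.spacing, (2.0, 2.0, 3.0))

    def test_mismatched_rows_raise(self, tmp_path):
        bad_dir = tmp_path / "a"
        self._write_series(bad_dir, nz=2, shuffle=False, rows_per_slice=[8, 16])
        with pytest.raises(ValueError, match="geometry"):
            read_volume(bad_dir, format="dicom_dir")


class TestCrop:
    def test_full_box_identity(self):
        vol = make_vol()
        box = BoundingBox((0, 0, 0), vol.shape)
        out = crop_volume(vol, box)
        np.testing.assert_array_equal(out.data, vol.data)

    def test_margin_crop_of_constant(self):
        vol = make_vol(value=7.0)
        out = crop_volume(vol, BoundingBox((1, 1, 1), (7, 7, 7)))
        assert out.shape == (6, 6, 6)
        assert np.all(out.data == 7.0)
        np.testing.assert_allclose(out.origin, (1.0, 1.0, 1.0))

    def test_crop_matches_index_arithmetic(self):
        rng = np.random.default_rng(2)
        vol = Volume3D(rng.uniform(0, 1, (10, 9, 8)), (1.0, 2.0, 3.0))
        box = BoundingBox((2, 1, 3), (7, 8, 6))
        out = crop_volume(vol, box)
        np.testing.assert_array_equal(out.data, vol.data[2:7, 1:8, 3:6])
        np.testing.assert_allclose(out.origin, (2.0, 2.0, 9.0))

    def test_crop_composition(self):
        rng = np.random.default_rng(3)
        vol = Volume3D(rng.uniform(0, 1, (12, 12, 12)), (1.0, 1.0, 1.0))
        a = BoundingBox((1, 2, 3), (11, 10, 12))
        b = BoundingBox((2, 1, 0), (8, 6, 7))
        composed = BoundingBox(
            tuple(x + y for x, y in zip(a.start, b.start)),
            tuple(x + y for x, y in zip(a.start, b.stop)),
        )
        step = crop_volume(crop_volume(vol, a), b)
        direct = crop_volume(vol, composed)
        np.testing.assert_array_equal(step.data, direct.data)
        np.testing.assert_allclose(step.origin, direct.origin)

    def test_box_outside_grid(self):
        with pytest.raises(ValueError):
            crop_volume(make_vol(), BoundingBox((0, 0, 0), (9, 8, 8)))


class TestResample:
    def test_same_shape_near_identity(self):
        rng = np.random.default_rng(4)
        vol = Volume3D(rng.uniform(0, 1, (8, 8, 8)), (1.0, 1.0, 1.0))
        out = resample_volume(vol, vol.shape)
        np.testing.assert_allclose(out.data, vol.data, atol=1e-9)

    @pytest.mark.parametrize("target", [(4, 4, 4), (16, 16, 16), (5, 9, 13)])
    def test_constant_stays_constant(self, target):
        out = resample_volume(make_vol(value=2.5), target)
        assert out.shape == target
        np.testing.assert_allclose(out.data, 2.5)

    def test_physical_extent_preserved(self):
        vol = make_vol((8, 10, 12), spacing=(1.0, 2.0, 3.0))
        out = resample_volume(vol, (16, 5, 7))
        np.testing.assert_allclose(out.physical_extent(), vol.physical_extent())

    def test_upsampled_ramp_matches_analytic(self):
        # linear field sampled at voxel centers; trilinear interpolation is exact
        n = 8
        x = np.arange(n, dtype=float)
        ramp = np.broadcast_to(x[:, None, None], (n, n, n)).copy()
        vol = Volume3D(ramp, (1.0, 1.0, 1.0))
        out = resample_volume(vol, (2 * n, n, n))
        # output voxel center i maps to input coordinate (i + 0.5)/2 - 0.5
        expected = (np.arange(2 * n) + 0.5) / 2.0 - 0.5
        expected = np.clip(expected, 0, n - 1)  # edge voxels replicate
        np.testing.assert_allclose(out.data[:, 4, 4], expected, atol=1e-9)

    def test_trilinear_bounded_by_input_range(self):
        rng = np.random.default_rng(5)
        vol = Volume3D(rng.uniform(1, 9, (6, 6, 6)), (1.0, 1.0, 1.0))
        out = resample_volume(vol, (13, 11, 7))
        assert out.data.min() >= vol.data.min() - 1e-12
        assert out.data.max() <= vol.data.max() + 1e-12

    def test_invalid_target(self):
        with pytest.raises(ValueError):
            resample_volume(make_vol(), (1, 8, 8))
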