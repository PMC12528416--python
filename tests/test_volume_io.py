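import warnings

import numpy as np
import pydicom
import pytest

from ctweigh import (
    AmbiguousSeriesError,
    CTVolume,
    InputError,
    MaskError,
    MetadataError,
    classify_voxels,
    generate_phantom,
    read_dicom_series,
    read_nifti_volume,
    write_mask_volume,
    write_phantom_dicom,
    write_volume_nifti,
)
from ctweigh.errors import GeometryWarning, HURangeWarning
from ctweigh.volume_io import series_metadata_row


def _write_series(volume, directory):
    write_phantom_dicom(volume, directory)
    return sorted(directory.iterdir())


class TestCTVolume:
    def test_spacing_must_be_positive(self):
        with pytest.raises(InputError):
            CTVolume(np.zeros((2, 4, 4)), 1.0, 1.0, 0.0, 1.0)

    def test_non_3d_rejected(self):
        with pytest.raises(InputError):
            CTVolume(np.zeros((4, 4)), 1.0, 1.0, 1.0, 1.0)

    def test_sub_floor_hu_warns_without_mutation(self):
        voxels = np.full((1, 4, 4), -2000.0)
        with pytest.warns(HURangeWarning):
            vol = CTVolume(voxels, 1.0, 1.0, 1.0, 1.0)
        assert vol.voxels.min() == -2000.0

    def test_slice_count_tracks_first_axis(self):
        vol = CTVolume(np.zeros((7, 4, 4)), 1.0, 1.0, 1.0, 1.0)
        assert vol.slice_count == 7


class TestDicomRoundTrip:
    def test_phantom_round_trip_identical(self, simple_body_spec, tmp_path):
        volume, _ = generate_phantom(simple_body_spec)
        _write_series(volume, tmp_path)
        back = read_dicom_series(tmp_path)
        assert np.array_equal(back.voxels, volume.voxels)
        for attr in ("pixel_spacing_row", "pixel_spacing_col", "slice_thickness", "slice_spacing"):
            assert getattr(back, attr) == pytest.approx(getattr(volume, attr), abs=1e-6)

    def test_rescale_identity_gives_zero_hu(self, tmp_path):
        # stored 1024 with slope 1 / intercept -1024 must read as 0 HU
        vol = CTVolume(np.zeros((3, 8, 8)), 1.0, 1.0, 1.0, 1.0)
        _write_series(vol, tmp_path)
        for path in tmp_path.iterdir():
            ds = pydicom.dcmread(path)
            assert ds.pixel_array.min() == ds.pixel_array.max() == -ds.RescaleIntercept
        back = read_dicom_series(tmp_path)
        assert np.all(back.voxels == 0.0)

    def test_submillimeter_slice_spacing_recovered(self, tmp_path):
        vol = CTVolume(np.zeros((3, 8, 8)), 0.625, 0.625, 0.625, 0.625)
        _write_series(vol, tmp_path)
        assert read_dicom_series(tmp_path).slice_spacing == pytest.approx(0.625)

    def test_air_hu_survives_rescale(self, tmp_path):
        vol = CTVolume(np.full((2, 4, 4), -1000.0), 1.0, 1.0, 1.0, 1.0)
        _write_series(vol, tmp_path)
        assert np.all(read_dicom_series(tmp_path).voxels == -1000.0)

    def test_shuffled_file_names_sorted_by_position(self, tmp_path):
        volume, _ = generate_phantom_distinct_slices()
        write_phantom_dicom(volume, tmp_path)
        # rename so lexicographic order is reversed relative to position
        files = sorted(tmp_path.iterdir())
        for i, path in enumerate(files):
            path.rename(tmp_path / f"renamed_{len(files) - i:03d}.dcm")
        back = read_dicom_series(tmp_path)
        assert np.array_equal(back.voxels, volume.voxels)

    def test_thickness_spacing_mismatch_and_gap_warning(self, tmp_path):
        # positions 0,3,6 with a thickness tag of 3.75
        vol = CTVolume(np.zeros((3, 8, 8)), 1.0, 1.0, 3.75, 3.0)
        _write_series(vol, tmp_path)
        back = read_dicom_series(tmp_path)
        assert back.slice_spacing == pytest.approx(3.0)
        assert back.slice_thickness == pytest.approx(3.75)

    def test_nonuniform_gaps_warn_median_used(self, tmp_path):
        vol = CTVolume(np.zeros((4, 8, 8)), 1.0, 1.0, 1.0, 1.0)
        _write_series(vol, tmp_path)
        # displace one slice's position by 20%
        files = sorted(tmp_path.iterdir())
        ds = pydicom.dcmread(files[-1])
        ds.ImagePositionPatient = [0.0, 0.0, float(ds.ImagePositionPatient[2]) + 0.2]
        ds.save_as(files[-1], enforce_file_format=True)
        with pytest.warns(GeometryWarning):
            back = read_dicom_series(tmp_path)
        assert back.slice_spacing == pytest.approx(1.0)

    def test_empty_directory_is_input_error(self, tmp_path):
        with pytest.raises(InputError):
            read_dicom_series(tmp_path)

    def test_mixed_series_uids_are_ambiguous(self, tmp_path):
        vol = CTVolume(np.zeros((2, 4, 4)), 1.0, 1.0, 1.0, 1.0)
        _write_series(vol, tmp_path / "a")
        _write_series(vol, tmp_path / "b")
        merged = tmp_path / "merged"
        merged.mkdir()
        for sub in ("a", "b"):
            for f in (tmp_path / sub).iterdir():
                (merged / f"{sub}_{f.name}").write_bytes(f.read_bytes())
        with pytest.raises(AmbiguousSeriesError):
            read_dicom_series(merged)

    def test_missing_pixel_spacing_is_metadata_error(self, tmp_path):
        vol = CTVolume(np.zeros((2, 4, 4)), 1.0, 1.0, 1.0, 1.0)
        files = _write_series(vol, tmp_path)
        for path in files:
            ds = pydicom.dcmread(path)
            del ds.PixelSpacing
            ds.save_as(path, enforce_file_format=True)
        with pytest.raises(MetadataError):
            read_dicom_series(tmp_path)

    def test_non_axial_orientation_rejected(self, tmp_path):
        vol = CTVolume(np.zeros((2, 4, 4)), 1.0, 1.0, 1.0, 1.0)
        files = _write_series(vol, tmp_path)
        for path in files:
            ds = pydicom.dcmread(path)
            ds.ImageOrientationPatient = [1.0, 0.0, 0.0, 0.0, 0.0, -1.0]  # coronal
            ds.save_as(path, enforce_file_format=True)
        with pytest.raises(InputError):
            read_dicom_series(tmp_path)


def generate_phantom_distinct_slices():
    """Phantom whose slices differ, so ordering mistakes are visible."""
    from ctweigh import PhantomComponent, PhantomSpec

    comps = [
        PhantomComponent("box", (float(k), 10.0, 10.0 + 3 * k), (0.4, 3.0, 3.0), 50.0, "muscle")
        for k in range(4)
    ]
    spec = PhantomSpec(image_rows=32, image_cols=32, slice_count=4, components=comps)
    return generate_phantom(spec)


class TestNifti:
    def test_round_trip_identity(self, simple_body, tmp_path):
        volume, _ = simple_body
        path = tmp_path / "vol.nii.gz"
        write_volume_nifti(volume, path)
        back = read_nifti_volume(path)
        assert np.array_equal(back.voxels, volume.voxels)
        assert back.pixel_spacing_row == pytest.approx(volume.pixel_spacing_row)
        assert back.slice_spacing == pytest.approx(volume.slice_spacing)

    def test_isotropic_spacings_all_equal(self, tmp_path):
        vol = CTVolume(np.zeros((3, 5, 6)), 1.0, 1.0, 1.0, 1.0)
        path = tmp_path / "iso.nii"
        write_volume_nifti(vol, path)
        back = read_nifti_volume(path)
        assert (
            back.pixel_spacing_row
            == back.pixel_spacing_col
            == back.slice_thickness
            == back.slice_spacing
            == 1.0
        )

    def test_4d_image_rejected(self, tmp_path):
        import nibabel as nib

        path = tmp_path / "vol4d.nii"
        nib.save(nib.Nifti1Image(np.zeros((4, 4, 4, 2), dtype=np.float32), np.eye(4)), path)
        with pytest.raises(InputError):
            read_nifti_volume(path)


class TestMaskWriting:
    def test_label_round_trip(self, simple_body, tmp_path):
        import nibabel as nib

        volume, truth = simple_body
        masks = classify_voxels(volume)
        path = tmp_path / "labels.nii.gz"
        write_mask_volume(masks, volume, path)
        labels = np.transpose(np.asanyarray(nib.load(path).dataobj), (2, 1, 0))
        assert (labels == 1).sum() == truth.voxel_counts["fat"]
        assert (labels == 2).sum() == truth.voxel_counts["muscle"]
        assert (labels == 3).sum() == truth.voxel_counts["bone"]

    def test_all_background_writes_zeros(self, tmp_path):
        import nibabel as nib

        vol = CTVolume(np.full((2, 4, 4), -1000.0), 1.0, 1.0, 1.0, 1.0)
        masks = classify_voxels(vol)
        path = tmp_path / "zeros.nii"
        write_mask_volume(masks, vol, path)
        assert np.all(np.asanyarray(nib.load(path).dataobj) == 0)

    def test_overlapping_masks_rejected(self, tmp_path):
        from ctweigh.tissue_weight import TissueMasks

        vol = CTVolume(np.zeros((1, 2, 2)), 1.0, 1.0, 1.0, 1.0)
        ones = np.ones((1, 2, 2), dtype=bool)
        masks = TissueMasks.__new__(TissueMasks)  # bypass the constructor's own check
        masks.fat = ones
        masks.muscle = ones
        masks.bone = np.zeros_like(ones)
        with pytest.raises(MaskError):
            write_mask_volume(masks, vol, tmp_path / "bad.nii")


def test_metadata_row_contents(simple_body):
    volume, _ = simple_body
    row = series_metadata_row(volume, "s1")
    assert row["slice_count"] == volume.slice_count
    assert row["hu_min"] == -1000.0
    assert row["slice_spacing_mm"] == volume.slice_spacing
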