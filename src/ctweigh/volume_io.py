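"""Reading and writing CT volumes.

The package-wide carrier is :class:`CTVolume`: a 3-D grid of Hounsfield
units indexed ``(slice, row, column)`` with row indices increasing downward
in the displayed image (so the patient table sits at high row indices),
plus the physical spacing metadata needed for volumetry.

DICOM series are read with :func:`read_dicom_series` (pydicom), NIfTI
volumes with :func:`read_nifti_volume` (nibabel).  Label masks are written
back out as NIfTI via :func:`write_mask_volume`.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .errors import (
    AmbiguousSeriesError,
    GeometryWarning,
    HURangeWarning,
    InputError,
    MaskError,
    MetadataError,
)

#: Minimum physically plausible HU after rescaling (air is -1000; scanners
#: pad with -1024).  Values below trigger a warning, never mutation.
HU_FLOOR = -1024.0

_AXIAL_ORIENTATION = np.array([1.0, 0.0, 0.0, 0.0, 1.0, 0.0])


@dataclass
class SubjectMeta:
    """Optional per-subject metadata used by torso-to-whole-body extrapolation."""

    sex: str = "unknown"  # "male" | "female" | "unknown"
    body_length_cm: Optional[float] = None
    reference_weight_kg: Optional[float] = None

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female", "unknown"):
            raise InputError(f"sex must be male/female/unknown, got {self.sex!r}")


@dataclass
class CTVolume:
    """A 3-D Hounsfield-unit grid with physical spacing metadata.

    Parameters
    ----------
    voxels
        HU values, shape ``(slice_count, rows, cols)``.
    pixel_spacing_row, pixel_spacing_col
        In-plane voxel size in mm (row step / column step).
    slice_thickness
        Reconstructed slab width in mm.
    slice_spacing
        Center-to-center distance between consecutive slices in mm.  This,
        not the thickness, enters voxel-volume computations.
    subject_meta
        Optional sex / body length / reference weight of the subject.
    """

    voxels: np.ndarray
    pixel_spacing_row: float
    pixel_spacing_col: float
    slice_thickness: float
    slice_spacing: float
    subject_meta: Optional[SubjectMeta] = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise InputError(f"voxels must be 3-D (slice,row,col), got {self.voxels.ndim}-D")
        for name in ("pixel_spacing_row", "pixel_spacing_col", "slice_thickness", "slice_spacing"):
            if not getattr(self, name) > 0:
                raise InputError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.voxels.size and float(self.voxels.min()) < HU_FLOOR:
            warnings.warn(
                f"voxel values below {HU_FLOOR} HU present (min {float(self.voxels.min()):.1f}); "
                "left unmodified",
                HURangeWarning,
                stacklevel=2,
            )

    @property
    def slice_count(self) -> int:
        return self.voxels.shape[0]

    @property
    def shape(self) -> tuple:
        return self.voxels.shape

    def copy(self) -> "CTVolume":
        return CTVolume(
            voxels=self.voxels.copy(),
            pixel_spacing_row=self.pixel_spacing_row,
            pixel_spacing_col=self.pixel_spacing_col,
            slice_thickness=self.slice_thickness,
            slice_spacing=self.slice_spacing,
            subject_meta=self.subject_meta,
        )


def _read_datasets(directory_path):
    import pydicom

    directory = Path(directory_path)
    if not directory.is_dir():
        raise InputError(f"not a directory: {directory}")
    datasets = []
    for name in sorted(os.listdir(directory)):
        path = directory / name
        if not path.is_file():
            continue
        try:
            ds = pydicom.dcmread(path)
        except Exception:
            continue  # non-DICOM clutter is ignored
        if getattr(ds, "Modality", "CT") != "CT":
            continue
        datasets.append(ds)
    if not datasets:
        raise InputError(f"no readable CT DICOM files in {directory}")
    return datasets


def _check_axial(ds) -> None:
    iop = getattr(ds, "ImageOrientationPatient", None)
    if iop is None:
        return  # assume axial when the tag is absent
    if not np.allclose(np.asarray(iop, dtype=float), _AXIAL_ORIENTATION, atol=1e-3):
        raise InputError(
            "non-axial slice orientation; this method is defined on axial acquisitions"
        )


def _slice_hu(ds) -> np.ndarray:
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    return ds.pixel_array.astype(np.float64) * slope + intercept


def _frames_from_dataset(ds):
    """Yield (z_position, 2-D HU array) for a single- or multi-frame dataset."""
    n_frames = int(getattr(ds, "NumberOfFrames", 1))
    if n_frames <= 1:
        _check_axial(ds)
        pos = getattr(ds, "ImagePositionPatient", None)
        z = float(pos[2]) if pos is not None else None
        yield z, _slice_hu(ds)
        return
    # Multi-frame: per-frame functional groups carry position when present.
    pixel = ds.pixel_array.astype(np.float64)
    if pixel.ndim == 2:
        pixel = pixel[None]
    groups = getattr(ds, "PerFrameFunctionalGroupsSequence", None)
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    for i in range(n_frames):
        z = None
        fslope, fintercept = slope, intercept
        if groups is not None and i < len(groups):
            g = groups[i]
            plane = getattr(g, "PlanePositionSequence", None)
            if plane:
                z = float(plane[0].ImagePositionPatient[2])
            transform = getattr(g, "PixelValueTransformationSequence", None)
            if transform:
                fslope = float(transform[0].RescaleSlope)
                fintercept = float(transform[0].RescaleIntercept)
        yield z, pixel[i] * fslope + fintercept


def _resolve_slice_spacing(z_positions, ds) -> float:
    """Median of consecutive position gaps; fallback to tags."""
    zs = [z for z in z_positions if z is not None]
    if len(zs) >= 2:
        gaps = np.diff(np.sort(np.asarray(zs, dtype=float)))
        gaps = gaps[gaps > 0]
        if gaps.size:
            median_gap = float(np.median(gaps))
            if np.any(np.abs(gaps - median_gap) > 0.01 * median_gap):
                warnings.warn(
                    "non-uniform slice gaps beyond 1% tolerance; using median gap "
                    f"{median_gap:.4g} mm",
                    GeometryWarning,
                    stacklevel=3,
                )
            return median_gap
    sbs = getattr(ds, "SpacingBetweenSlices", None)
    if sbs is not None:
        return float(sbs)
    st = getattr(ds, "SliceThickness", None)
    if st is not None:
        return float(st)
    raise MetadataError("cannot determine slice spacing: no positions, no spacing/thickness tags")


def read_dicom_series(directory_path) -> CTVolume:
    """Read a directory of CT DICOM files into a :class:`CTVolume`.

    Slices are sorted by the z-component of Image Position (Patient) —
    spatial order, not filename or instance number.  Stored values are
    converted to HU via each file's rescale slope/intercept.  Slice spacing
    is the median of consecutive position gaps, falling back to the Spacing
    Between Slices tag, then to Slice Thickness.

    Raises
    ------
    InputError
        Empty directory, or non-axial orientation.
    AmbiguousSeriesError
        Files from more than one series identifier.
    MetadataError
        Pixel spacing missing.
    """
    datasets = _read_datasets(directory_path)

    series_uids = {str(getattr(ds, "SeriesInstanceUID", "")) for ds in datasets}
    if len(series_uids) > 1:
        raise AmbiguousSeriesError(
            f"directory mixes {len(series_uids)} series identifiers: {sorted(series_uids)}"
        )

    frames = []  # (z, hu_2d)
    for ds in datasets:
        frames.extend(_frames_from_dataset(ds))

    if all(z is not None for z, _ in frames):
        frames.sort(key=lambda t: t[0])

    ref = datasets[0]
    spacing = getattr(ref, "PixelSpacing", None)
    if spacing is None:
        raise MetadataError("PixelSpacing tag missing")
    pixel_spacing_row, pixel_spacing_col = float(spacing[0]), float(spacing[1])

    slice_spacing = _resolve_slice_spacing([z for z, _ in frames], ref)
    slice_thickness = float(getattr(ref, "SliceThickness", slice_spacing))

    voxels = np.stack([hu for _, hu in frames], axis=0)
    return CTVolume(
        voxels=voxels,
        pixel_spacing_row=pixel_spacing_row,
        pixel_spacing_col=pixel_spacing_col,
        slice_thickness=slice_thickness,
        slice_spacing=slice_spacing,
    )


def read_nifti_volume(file_path) -> CTVolume:
    """Read a 3-D NIfTI image into a :class:`CTVolume`.

    Voxel sizes come from the affine; the axial voxel size doubles as both
    slice spacing and slice thickness (NIfTI carries no separate thickness).
    The array is normalized to ``(slice, row, column)`` order.
    """
    import nibabel as nib

    img = nib.load(str(file_path))
    if img.ndim != 3:
        raise InputError(f"expected a 3-D NIfTI image, got {img.ndim}-D")
    zooms = img.header.get_zooms()[:3]
    data = np.asanyarray(img.dataobj).astype(np.float64)
    # nibabel order is (col, row, slice) for our writer's diagonal affine.
    voxels = np.transpose(data, (2, 1, 0))
    return CTVolume(
        voxels=voxels,
        pixel_spacing_row=float(zooms[1]),
        pixel_spacing_col=float(zooms[0]),
        slice_thickness=float(zooms[2]),
        slice_spacing=float(zooms[2]),
    )


def _nifti_affine(volume: CTVolume) -> np.ndarray:
    return np.diag(
        [volume.pixel_spacing_col, volume.pixel_spacing_row, volume.slice_spacing, 1.0]
    )


def write_volume_nifti(volume: CTVolume, file_path) -> None:
    """Write a CTVolume as a NIfTI-1 image (float32 HU)."""
    import nibabel as nib

    data = np.transpose(volume.voxels, (2, 1, 0)).astype(np.float32)
    nib.save(nib.Nifti1Image(data, _nifti_affine(volume)), str(file_path))


def write_mask_volume(masks, volume: CTVolume, file_path) -> None:
    """Write tissue masks as a NIfTI label image.

    Labels: 0 background, 1 fat, 2 muscle, 3 bone.

    Raises
    ------
    MaskError
        If the masks overlap or are not aligned to ``volume``.
    """
    import nibabel as nib

    for m in (masks.fat, masks.muscle, masks.bone):
        if m.shape != volume.voxels.shape:
            raise MaskError("masks are not aligned to the volume")
    overlap = (
        masks.fat.astype(np.uint8) + masks.muscle.astype(np.uint8) + masks.bone.astype(np.uint8)
    )
    if overlap.max(initial=0) > 1:
        raise MaskError("tissue masks overlap; labels would be ambiguous")
    labels = np.zeros(volume.voxels.shape, dtype=np.uint8)
    labels[masks.fat] = 1
    labels[masks.muscle] = 2
    labels[masks.bone] = 3
    data = np.transpose(labels, (2, 1, 0))
    nib.save(nib.Nifti1Image(data, _nifti_affine(volume)), str(file_path))


def series_metadata_row(volume: CTVolume, series_id: str = "") -> dict:
    """One CSV-ready metadata row for a series: spacings, slice count, HU range."""
    return {
        "series_id": series_id,
        "slice_count": volume.slice_count,
        "rows": volume.voxels.shape[1],
        "cols": volume.voxels.shape[2],
        "pixel_spacing_row_mm": volume.pixel_spacing_row,
        "pixel_spacing_col_mm": volume.pixel_spacing_col,
        "slice_thickness_mm": volume.slice_thickness,
        "slice_spacing_mm": volume.slice_spacing,
        "hu_min": float(volume.voxels.min()) if volume.voxels.size else float("nan"),
        "hu_max": float(volume.voxels.max()) if volume.voxels.size else float("nan"),
    }
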