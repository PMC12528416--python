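"""Synthetic CT phantoms with an analytic weight oracle.

A phantom is an axial CT volume containing simple geometric bodies
(elliptical cylinders, boxes) of fat/muscle/bone HU resting above a
parabolic high-density table band, over a -1000 HU air background.  The
ground truth counts *rasterized* voxels — not idealized continuous shape
volumes — so a correct pipeline reproduces it exactly on noise-free input
and discretization error never enters the comparison.

Also provides :func:`write_phantom_dicom` (round-trippable DICOM series)
and :func:`standard_cohort` (synthetic torso/whole-body cohorts for
scaling-factor calibration tests).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import InputError, SpecError
from .tissue_weight import TISSUE_CLASSES, TissueClassConfig
from .volume_io import CTVolume


@dataclass(frozen=True)
class PhantomComponent:
    """One body component: an elliptical cylinder (extruded along the slice
    axis) or an axis-aligned box, in voxel units.

    ``center`` and ``axes`` are (slice, row, col) triples; for the ellipse
    the in-plane cross-section is ((i-i0)/ai)² + ((j-j0)/aj)² <= 1 on slices
    with |k-k0| <= ak.  ``hu`` must lie inside the declared class's HU
    interval so the oracle is exact at zero noise.
    """

    shape: str  # "ellipse" | "box"
    center: Tuple[float, float, float]
    axes: Tuple[float, float, float]
    hu: float
    tissue_class: str  # "fat" | "muscle" | "bone" | "air"

    def __post_init__(self) -> None:
        if self.shape not in ("ellipse", "box"):
            raise SpecError(f"shape must be ellipse or box, got {self.shape!r}")
        if self.tissue_class not in TISSUE_CLASSES + ("air",):
            raise SpecError(f"unknown tissue class {self.tissue_class!r}")
        if any(a <= 0 for a in self.axes):
            raise SpecError("component axes must be positive")


@dataclass(frozen=True)
class TableSpec:
    """Parabolic table band: top edge row = a·col² + b·col + c, filled
    downward for ``band_height`` rows at ``hu``."""

    a: float
    b: float
    c: float
    band_height: int = 8
    hu: float = 250.0

    def top_row(self, col: np.ndarray) -> np.ndarray:
        return self.a * col**2 + self.b * col + self.c


@dataclass
class PhantomSpec:
    """Declarative phantom description; see module docstring."""

    image_rows: int = 128
    image_cols: int = 128
    slice_count: int = 12
    pixel_spacing_row: float = 1.0
    pixel_spacing_col: float = 1.0
    slice_thickness: float = 1.0
    slice_spacing: float = 1.0
    components: List[PhantomComponent] = field(default_factory=list)
    table: Optional[TableSpec] = None
    background_hu: float = -1000.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise SpecError("noise_sd must be >= 0")
        if min(self.image_rows, self.image_cols, self.slice_count) < 1:
            raise SpecError("grid dimensions must be positive")


@dataclass(frozen=True)
class PhantomTruth:
    """Analytic ground truth from rasterized voxel counts."""

    voxel_counts: dict
    volumes_cm3: dict
    masses_kg: dict
    total_mass_kg: float


def _rasterize_component(comp: PhantomComponent, shape: tuple) -> np.ndarray:
    ks, rows, cols = shape
    k = np.arange(ks, dtype=float)[:, None, None]
    i = np.arange(rows, dtype=float)[None, :, None]
    j = np.arange(cols, dtype=float)[None, None, :]
    k0, i0, j0 = comp.center
    ak, ai, aj = comp.axes
    along = np.abs(k - k0) <= ak
    if comp.shape == "box":
        return along & (np.abs(i - i0) <= ai) & (np.abs(j - j0) <= aj)
    return along & (((i - i0) / ai) ** 2 + ((j - j0) / aj) ** 2 <= 1.0)


def _rasterize_table(table: TableSpec, shape: tuple) -> np.ndarray:
    ks, rows, cols = shape
    top = np.ceil(table.top_row(np.arange(cols, dtype=float)))
    band = np.zeros((rows, cols), dtype=bool)
    r = np.arange(rows, dtype=float)[:, None]
    band = (r >= top[None, :]) & (r < top[None, :] + table.band_height)
    return np.broadcast_to(band[None, :, :], shape).copy()


def generate_phantom(
    spec: PhantomSpec,
    config: Optional[TissueClassConfig] = None,
) -> Tuple[CTVolume, PhantomTruth]:
    """Rasterize a phantom spec and return the volume plus its oracle.

    The grid is filled with ``background_hu``, components are painted in
    order (later components overwrite earlier ones; ground truth counts
    the final label of each voxel), then the table band is drawn.  A
    component overlapping the table band is a :class:`SpecError`.  Seeded
    Gaussian noise is added last, after the oracle is computed.
    """
    config = config or TissueClassConfig()
    shape = (spec.slice_count, spec.image_rows, spec.image_cols)

    for comp in spec.components:
        if comp.tissue_class != "air" and not config.contains(comp.tissue_class, comp.hu):
            raise SpecError(
                f"component HU {comp.hu} lies outside the {comp.tissue_class} interval "
                f"{config.interval(comp.tissue_class)[:2]}; oracle would not be exact"
            )

    hu = np.full(shape, spec.background_hu, dtype=np.float64)
    labels = np.zeros(shape, dtype=np.int8)  # 0 air, 1 fat, 2 muscle, 3 bone
    class_index = {"air": 0, "fat": 1, "muscle": 2, "bone": 3}

    table_mask = _rasterize_table(spec.table, shape) if spec.table is not None else None

    for comp in spec.components:
        mask = _rasterize_component(comp, shape)
        if table_mask is not None and np.any(mask & table_mask):
            raise SpecError(f"component {comp} overlaps the table band")
        hu[mask] = comp.hu
        labels[mask] = class_index[comp.tissue_class]

    if table_mask is not None and spec.table is not None:
        hu[table_mask] = spec.table.hu

    voxel_vol_cm3 = (
        spec.pixel_spacing_row * spec.pixel_spacing_col * spec.slice_spacing / 1000.0
    )
    counts = {c: int((labels == class_index[c]).sum()) for c in TISSUE_CLASSES}
    volumes = {c: counts[c] * voxel_vol_cm3 for c in TISSUE_CLASSES}
    masses = {c: volumes[c] * config.density(c) / 1000.0 for c in TISSUE_CLASSES}
    truth = PhantomTruth(
        voxel_counts=counts,
        volumes_cm3=volumes,
        masses_kg=masses,
        total_mass_kg=sum(masses.values()),
    )

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        hu = hu + rng.normal(0.0, spec.noise_sd, size=shape)

    volume = CTVolume(
        voxels=hu,
        pixel_spacing_row=spec.pixel_spacing_row,
        pixel_spacing_col=spec.pixel_spacing_col,
        slice_thickness=spec.slice_thickness,
        slice_spacing=spec.slice_spacing,
    )
    return volume, truth


def body_with_table(
    *,
    rows: int = 128,
    cols: int = 128,
    slices: int = 10,
    spacing: Tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0),
    table: Optional[TableSpec] = None,
    air_gap_voxels: int = 10,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> PhantomSpec:
    """Convenience builder: a torso-like stack (fat shell, muscle core, bone
    rod) centered above an optional parabolic table.

    ``spacing`` is (pixel_row, pixel_col, thickness, slice_spacing) in mm.
    The body's lowest row keeps ``air_gap_voxels`` of air above the highest
    point of the table band.
    """
    if table is None:
        table = TableSpec(a=0.0, b=0.0, c=rows - 18.0, band_height=8, hu=250.0)
    cols_idx = np.arange(cols, dtype=float)
    table_top_min = float(np.min(np.ceil(table.top_row(cols_idx))))
    body_bottom = table_top_min - air_gap_voxels - 1
    body_ri = min((rows * 0.33), (body_bottom - 4) / 2.0)
    if body_ri < 6:
        raise SpecError("not enough room above the table for a body")
    body_i0 = body_bottom - body_ri
    k0 = (slices - 1) / 2.0
    comps = [
        PhantomComponent(
            "ellipse", (k0, body_i0, (cols - 1) / 2.0), (slices, body_ri, cols * 0.35), -100.0, "fat"
        ),
        PhantomComponent(
            "ellipse",
            (k0, body_i0, (cols - 1) / 2.0),
            (slices, body_ri * 0.62, cols * 0.22),
            50.0,
            "muscle",
        ),
        PhantomComponent(
            "ellipse",
            (k0, body_i0, (cols - 1) / 2.0),
            (slices, body_ri * 0.22, cols * 0.07),
            400.0,
            "bone",
        ),
    ]
    return PhantomSpec(
        image_rows=rows,
        image_cols=cols,
        slice_count=slices,
        pixel_spacing_row=spacing[0],
        pixel_spacing_col=spacing[1],
        slice_thickness=spacing[2],
        slice_spacing=spacing[3],
        components=comps,
        table=table,
        noise_sd=noise_sd,
        seed=seed,
    )


# --------------------------------------------------------------------------
# DICOM writing


def write_phantom_dicom(volume: CTVolume, directory_path) -> None:
    """Write one CT DICOM file per slice, re-readable by ``read_dicom_series``.

    Rescale intercept is set to the (floored) HU minimum with slope 1, so
    stored values are non-negative integers; HU are therefore quantized to
    1 HU on disk (exact for integer-valued phantoms).
    """
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

    directory = Path(directory_path)
    try:
        directory.mkdir(parents=True, exist_ok=True)
        if not directory.is_dir():
            raise OSError
    except OSError as exc:
        raise InputError(f"cannot write to directory {directory}: {exc}") from exc

    intercept = float(math.floor(volume.voxels.min())) if volume.voxels.size else -1024.0
    series_uid = generate_uid()
    study_uid = generate_uid()
    frame_uid = generate_uid()

    for k in range(volume.slice_count):
        stored = np.round(volume.voxels[k] - intercept).astype(np.uint16)
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\x00" * 128)
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.Modality = "CT"
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.FrameOfReferenceUID = frame_uid
        ds.PatientName = "PHANTOM^SYNTHETIC"
        ds.PatientID = "PHANTOM"
        ds.InstanceNumber = k + 1
        ds.ImagePositionPatient = [0.0, 0.0, float(k * volume.slice_spacing)]
        ds.ImageOrientationPatient = [1.0, 0.0, 0.0, 0.0, 1.0, 0.0]
        ds.PixelSpacing = [volume.pixel_spacing_row, volume.pixel_spacing_col]
        ds.SliceThickness = volume.slice_thickness
        ds.SpacingBetweenSlices = volume.slice_spacing
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = intercept
        ds.Rows, ds.Columns = stored.shape
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.PixelData = stored.tobytes()
        ds.save_as(directory / f"slice_{k:04d}.dcm", enforce_file_format=True)


# --------------------------------------------------------------------------
# Synthetic cohorts for scaling-factor calibration

COHORT_COLUMNS = (
    "subject_id",
    "sex",
    "torso_weight_kg",
    "reference_weight_kg",
    "scan_length_cm",
    "body_length_cm",
)


def standard_cohort(
    n_subjects: int,
    seed: int,
    sex_ratio: float = 0.5,
    sf_true: float = 0.4182,
    x_true: float = 0.269,
    noise_sd: float = 0.0,
) -> pd.DataFrame:
    """Generate a synthetic calibration cohort.

    Per subject: total weight ~ U(45, 120) kg, body length ~ U(150, 195) cm,
    relative scan length r = x_true + d with d ~ U(-0.08, 0.08) re-centered
    so the sample mean of r equals x_true exactly, and torso weight
    total × (sf_true + r − x_true) × (1 + ε), ε ~ N(0, noise_sd).  The
    re-centering makes the mean torso/total ratio equal sf_true exactly at
    zero noise, so calibration recovers the generating parameters without
    sampling bias.
    """
    if n_subjects < 2:
        raise InputError("a cohort needs at least 2 subjects")
    if not 0 < sf_true < 1:
        raise InputError("sf_true must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    total = rng.uniform(45.0, 120.0, n_subjects)
    body_length = rng.uniform(150.0, 195.0, n_subjects)
    dev = rng.uniform(-0.08, 0.08, n_subjects)
    dev = dev - dev.mean()
    r = x_true + dev
    ratio = sf_true + (r - x_true)
    torso = total * ratio
    if noise_sd > 0:
        torso = torso * (1.0 + rng.normal(0.0, noise_sd, n_subjects))
    sex = np.where(rng.random(n_subjects) < sex_ratio, "male", "female")
    return pd.DataFrame(
        {
            "subject_id": [f"S{i:04d}" for i in range(n_subjects)],
            "sex": sex,
            "torso_weight_kg": torso,
            "reference_weight_kg": total,
            "scan_length_cm": r * body_length,
            "body_length_cm": body_length,
        }
    )
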