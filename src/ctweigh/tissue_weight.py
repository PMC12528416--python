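"""HU-threshold tissue segmentation and density-weighted volumetry.

Three tissue classes are segmented by Hounsfield-unit intervals — fat in
[-190, -30] HU, muscle in (-30, 150] HU, bone above 150 HU — and converted
to mass with standard densities (fat 0.94, muscle 1.06, bone 1.85 g/cm³).
Voxels below the fat floor (air, lung, gas) contribute no mass.

Boundary convention
-------------------
Published integer-HU interval pairs like "fat -190..-30, muscle -31..150"
abut ambiguously once HU are floats.  The convention here is half-open:
fat = [fat_lo, fat_hi] closed, muscle = (fat_hi, muscle_hi], bone =
(muscle_hi, bone_hi or inf).  All boundaries are config keys, so the
literal integer reading remains selectable by shifting ``fat_hi``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import GeometryWarning, InputError, MaskError
from .volume_io import CTVolume

TISSUE_CLASSES = ("fat", "muscle", "bone")


@dataclass(frozen=True)
class TissueClassConfig:
    """HU thresholds and tissue densities for segmentation and weighting.

    Defaults follow the quantitative-CT standard: fat [-190, -30] HU at
    0.94 g/cm³, muscle (-30, 150] HU at 1.06 g/cm³, bone > 150 HU at
    1.85 g/cm³, no upper bone bound unless ``bone_hi`` is set.
    """

    fat_lo: float = -190.0
    fat_hi: float = -30.0
    muscle_hi: float = 150.0
    bone_hi: Optional[float] = None
    density_fat: float = 0.94
    density_muscle: float = 1.06
    density_bone: float = 1.85

    def __post_init__(self) -> None:
        if not (self.fat_lo < self.fat_hi < self.muscle_hi):
            raise InputError(
                f"thresholds must satisfy fat_lo < fat_hi < muscle_hi, got "
                f"{self.fat_lo} / {self.fat_hi} / {self.muscle_hi}"
            )
        if self.bone_hi is not None and not self.bone_hi > self.muscle_hi:
            raise InputError("bone_hi must exceed muscle_hi")
        for name in ("density_fat", "density_muscle", "density_bone"):
            if not getattr(self, name) > 0:
                raise InputError(f"{name} must be > 0")

    def density(self, tissue_class: str) -> float:
        return getattr(self, f"density_{tissue_class}")

    def interval(self, tissue_class: str) -> tuple:
        """(lo, hi, lo_closed) of the class's HU interval."""
        if tissue_class == "fat":
            return (self.fat_lo, self.fat_hi, True)
        if tissue_class == "muscle":
            return (self.fat_hi, self.muscle_hi, False)
        if tissue_class == "bone":
            hi = np.inf if self.bone_hi is None else self.bone_hi
            return (self.muscle_hi, hi, False)
        raise InputError(f"unknown tissue class {tissue_class!r}")

    def contains(self, tissue_class: str, hu: float) -> bool:
        lo, hi, lo_closed = self.interval(tissue_class)
        return (lo <= hu if lo_closed else lo < hu) and hu <= hi


@dataclass
class TissueMasks:
    """Pairwise-disjoint boolean masks for fat, muscle and bone."""

    fat: np.ndarray
    muscle: np.ndarray
    bone: np.ndarray

    def __post_init__(self) -> None:
        shapes = {self.fat.shape, self.muscle.shape, self.bone.shape}
        if len(shapes) != 1:
            raise MaskError("fat/muscle/bone masks must share one shape")
        stacked = (
            self.fat.astype(np.uint8) + self.muscle.astype(np.uint8) + self.bone.astype(np.uint8)
        )
        if stacked.max(initial=0) > 1:
            raise MaskError("tissue masks must be pairwise disjoint")

    def counts(self) -> dict:
        return {
            "fat": int(self.fat.sum()),
            "muscle": int(self.muscle.sum()),
            "bone": int(self.bone.sum()),
        }


@dataclass(frozen=True)
class WeightEstimate:
    """Per-class volumes (cm³) and masses (kg) plus the total mass."""

    volume_fat: float
    volume_muscle: float
    volume_bone: float
    mass_fat: float
    mass_muscle: float
    mass_bone: float
    total_mass: float
    voxel_volume: float

    def as_dict(self) -> dict:
        return {
            "volume_fat_cm3": self.volume_fat,
            "volume_muscle_cm3": self.volume_muscle,
            "volume_bone_cm3": self.volume_bone,
            "mass_fat_kg": self.mass_fat,
            "mass_muscle_kg": self.mass_muscle,
            "mass_bone_kg": self.mass_bone,
            "total_mass_kg": self.total_mass,
            "voxel_volume_cm3": self.voxel_volume,
        }


def classify_voxels(volume: CTVolume, config: Optional[TissueClassConfig] = None) -> TissueMasks:
    """Segment a volume into fat/muscle/bone by HU thresholds.

    fat := fat_lo <= HU <= fat_hi; muscle := fat_hi < HU <= muscle_hi;
    bone := HU > muscle_hi (and <= bone_hi when set).  Everything else —
    air below the fat floor, metal above ``bone_hi`` — is unclassified.
    """
    config = config or TissueClassConfig()
    hu = volume.voxels
    fat = (hu >= config.fat_lo) & (hu <= config.fat_hi)
    muscle = (hu > config.fat_hi) & (hu <= config.muscle_hi)
    bone = hu > config.muscle_hi
    if config.bone_hi is not None:
        bone &= hu <= config.bone_hi
    return TissueMasks(fat=fat, muscle=muscle, bone=bone)


def voxel_volume(volume: CTVolume) -> float:
    """Physical voxel volume in cm³: row spacing × column spacing × slice spacing.

    Slice *spacing* is the geometric truth — overlapping slabs (thickness
    larger than spacing) would otherwise double-count mass; that regime
    raises a :class:`GeometryWarning` because interpolation artifacts can
    still bias HU-based weighting.
    """
    if volume.slice_thickness > volume.slice_spacing:
        warnings.warn(
            f"slice thickness ({volume.slice_thickness} mm) exceeds slice spacing "
            f"({volume.slice_spacing} mm): overlapping slabs, partial-volume effects likely",
            GeometryWarning,
            stacklevel=2,
        )
    return (
        volume.pixel_spacing_row * volume.pixel_spacing_col * volume.slice_spacing
    ) / 1000.0  # mm³ -> cm³


def estimate_weight(
    masks: TissueMasks,
    volume: CTVolume,
    config: Optional[TissueClassConfig] = None,
) -> WeightEstimate:
    """Convert voxel counts to volumes and masses.

    Per class: volume = count × voxel volume (cm³); mass = volume × density
    / 1000 (kg).  The total is the exact sum of the three class masses.
    """
    config = config or TissueClassConfig()
    if masks.fat.shape != volume.voxels.shape:
        raise MaskError("masks are not congruent with the volume")
    vv = voxel_volume(volume)
    counts = masks.counts()
    volumes = {c: counts[c] * vv for c in TISSUE_CLASSES}
    massess = {c: volumes[c] * config.density(c) / 1000.0 for c in TISSUE_CLASSES}
    return WeightEstimate(
        volume_fat=volumes["fat"],
        volume_muscle=volumes["muscle"],
        volume_bone=volumes["bone"],
        mass_fat=massess["fat"],
        mass_muscle=massess["muscle"],
        mass_bone=massess["bone"],
        total_mass=massess["fat"] + massess["muscle"] + massess["bone"],
        voxel_volume=vv,
    )


def weigh_volume(volume: CTVolume, config: Optional[TissueClassConfig] = None) -> WeightEstimate:
    """Classify and weigh in one step."""
    config = config or TissueClassConfig()
    return estimate_weight(classify_voxels(volume, config), volume, config)


_SWEEPABLE = (
    "fat_lo",
    "fat_hi",
    "muscle_hi",
    "bone_hi",
    "density_fat",
    "density_muscle",
    "density_bone",
)


def sensitivity_sweep(
    volume: CTVolume,
    parameter_name: str,
    value_grid: Sequence[float],
    config: Optional[TissueClassConfig] = None,
) -> pd.DataFrame:
    """Re-estimate total mass while varying one threshold or density.

    Returns a table with one row per grid value: ``(value, total_mass_kg)``
    plus the per-class masses, all other parameters held at ``config``.
    Grid values that violate the threshold-ordering invariants raise
    :class:`InputError`.
    """
    if parameter_name not in _SWEEPABLE:
        raise InputError(f"parameter_name must be one of {_SWEEPABLE}, got {parameter_name!r}")
    config = config or TissueClassConfig()
    rows = []
    for value in value_grid:
        try:
            cfg = replace(config, **{parameter_name: value})
        except InputError as exc:
            raise InputError(f"grid value {value} for {parameter_name}: {exc}") from exc
        est = weigh_volume(volume, cfg)
        rows.append(
            {
                "value": value,
                "total_mass_kg": est.total_mass,
                "mass_fat_kg": est.mass_fat,
                "mass_muscle_kg": est.mass_muscle,
                "mass_bone_kg": est.mass_bone,
            }
        )
    return pd.DataFrame(rows)
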