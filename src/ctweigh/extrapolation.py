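"""Torso-to-whole-body weight extrapolation and scaling-factor calibration.

A torso scan captures only part of the body, so the CT-derived torso mass
is scaled up: ``total = torso / sf`` where the scaling factor *sf* is the
mean ratio of CT torso mass to measured total mass over a calibration
cohort (overall and per sex).  The corrected scaling factor adjusts for
how much of the body the scan actually covered,

    csf = sf + (scan_length / body_length − x),

with the offset *x* fitted by minimizing the absolute mean difference
between extrapolated and reference weights.  Default factors: overall
0.4182, male 0.4222, female 0.4144, x = 0.269.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .errors import DomainError, InputError, SearchError
from .volume_io import CTVolume

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScalingConfig:
    """Calibrated torso-to-whole-body scaling factors."""

    sf_overall: float = 0.4182
    sf_male: float = 0.4222
    sf_female: float = 0.4144
    offset_x: float = 0.269

    def __post_init__(self) -> None:
        for name in ("sf_overall", "sf_male", "sf_female", "offset_x"):
            if not 0 < getattr(self, name) < 1:
                raise DomainError(f"{name} must lie in (0, 1)")

    def sf_for(self, sex: str, sex_specific: bool = True) -> float:
        if sex_specific and sex == "male":
            return self.sf_male
        if sex_specific and sex == "female":
            return self.sf_female
        if sex not in ("male", "female"):
            logger.info("sex unknown; using overall scaling factor %.4f", self.sf_overall)
        return self.sf_overall


@dataclass(frozen=True)
class CohortRecord:
    """One calibration subject: CT torso mass vs measured total weight."""

    subject_id: str
    sex: str = "unknown"
    torso_weight: float = 0.0  # kg, CT-estimated
    reference_weight: float = 0.0  # kg, measured
    scan_length: Optional[float] = None  # cm
    body_length: Optional[float] = None  # cm

    def __post_init__(self) -> None:
        if not self.torso_weight > 0 or not self.reference_weight > 0:
            raise InputError(f"{self.subject_id}: weights must be > 0")
        if self.scan_length is not None and self.body_length is not None:
            if not 0 < self.scan_length <= self.body_length:
                raise InputError(
                    f"{self.subject_id}: need 0 < scan_length <= body_length, got "
                    f"{self.scan_length} / {self.body_length}"
                )


Cohort = Union[Sequence[CohortRecord], pd.DataFrame]


def cohort_from_dataframe(table: pd.DataFrame) -> List[CohortRecord]:
    """Convert a cohort CSV table (columns subject_id, sex, torso_weight_kg,
    reference_weight_kg, scan_length_cm, body_length_cm) to records."""
    records = []
    for row in table.itertuples(index=False):
        records.append(
            CohortRecord(
                subject_id=str(row.subject_id),
                sex=str(row.sex),
                torso_weight=float(row.torso_weight_kg),
                reference_weight=float(row.reference_weight_kg),
                scan_length=float(row.scan_length_cm)
                if "scan_length_cm" in table.columns and pd.notna(row.scan_length_cm)
                else None,
                body_length=float(row.body_length_cm)
                if "body_length_cm" in table.columns and pd.notna(row.body_length_cm)
                else None,
            )
        )
    return records


def _as_records(cohort: Cohort) -> List[CohortRecord]:
    if isinstance(cohort, pd.DataFrame):
        return cohort_from_dataframe(cohort)
    return list(cohort)


def extrapolate_sf(torso_weight: float, sf: float) -> float:
    """Whole-body weight from torso mass: ``torso_weight / sf``."""
    if not torso_weight > 0:
        raise InputError("torso_weight must be > 0")
    if not 0 < sf < 1:
        raise DomainError(f"sf must lie in (0, 1), got {sf}")
    return torso_weight / sf


def corrected_scaling_factor(
    sf: float,
    scan_length: float,
    body_length: float,
    offset_x: float,
) -> float:
    """csf = sf + (scan_length/body_length − x); must stay inside (0, 1)."""
    if not (scan_length > 0 and body_length > 0):
        raise InputError("lengths must be > 0")
    if scan_length > body_length:
        raise InputError("scan_length cannot exceed body_length")
    csf = sf + (scan_length / body_length - offset_x)
    if not 0 < csf < 1:
        raise DomainError(
            f"corrected scaling factor {csf:.4f} outside (0, 1): "
            "scan length and body length are inconsistent"
        )
    return csf


def scan_length_from_volume(volume: CTVolume) -> float:
    """Scan length in cm: slice count × slice thickness.

    This is the conventional definition even though volumetry uses slice
    spacing; when thickness and spacing differ the discrepancy is logged.
    """
    if abs(volume.slice_thickness - volume.slice_spacing) > 1e-9:
        logger.info(
            "scan length uses slice thickness (%.4g mm) though spacing is %.4g mm",
            volume.slice_thickness,
            volume.slice_spacing,
        )
    return volume.slice_count * volume.slice_thickness / 10.0


def calibrate_sf(cohort: Cohort, group: str = "all") -> float:
    """Mean torso-to-total mass ratio over a cohort group (all/male/female)."""
    if group not in ("all", "male", "female"):
        raise InputError(f"group must be all/male/female, got {group!r}")
    records = _as_records(cohort)
    if group != "all":
        records = [r for r in records if r.sex == group]
    if len(records) < 2:
        raise InputError(f"group {group!r} needs at least 2 records, has {len(records)}")
    ratios = np.array([r.torso_weight / r.reference_weight for r in records])
    return float(ratios.mean())


def calibrate_offset_x(
    cohort: Cohort,
    sf: float,
    search_interval: Tuple[float, float] = (0.0, 0.6),
    tolerance: float = 1e-4,
) -> float:
    """Fit the csf offset x by minimizing |mean(estimated − reference)|.

    The estimated weight of subject i under candidate x is
    ``torso_i / (sf + r_i − x)`` with r_i = scan_length/body_length.  The
    signed mean difference is strictly increasing in x wherever feasible,
    so the search runs a 1e-3-step grid over ``search_interval`` (x with
    any csf outside (0, 1) excluded), then bisects the bracketing sign
    change down to ``tolerance``.  Ties break toward smaller x.
    """
    records = _as_records(cohort)
    if len(records) < 2:
        raise InputError("offset calibration needs at least 2 records")
    for r in records:
        if r.scan_length is None or r.body_length is None:
            raise InputError(f"{r.subject_id}: scan_length and body_length required")
    torso = np.array([r.torso_weight for r in records])
    ref = np.array([r.reference_weight for r in records])
    rel = np.array([r.scan_length / r.body_length for r in records])

    def signed_mean(x: float) -> float:
        csf = sf + rel - x
        if np.any(csf <= 0) or np.any(csf >= 1):
            return np.nan
        return float(np.mean(torso / csf - ref))

    lo, hi = search_interval
    grid = np.arange(lo, hi + 1e-12, 1e-3)
    values = np.array([signed_mean(x) for x in grid])
    feasible = np.isfinite(values)
    if not feasible.any():
        raise SearchError("no feasible x in the search interval (csf left (0,1) everywhere)")
    objective = np.abs(np.where(feasible, values, np.inf))
    best_idx = int(np.argmin(objective))  # argmin takes the first (smallest x) tie

    # bracket a sign change adjacent to the best grid point, then bisect
    for left in (best_idx - 1, best_idx):
        right = left + 1
        if left < 0 or right >= len(grid):
            continue
        fl, fr = values[left], values[right]
        if np.isfinite(fl) and np.isfinite(fr) and fl * fr <= 0:
            a, b = float(grid[left]), float(grid[right])
            fa = fl
            while b - a > tolerance:
                m = 0.5 * (a + b)
                fm = signed_mean(m)
                if fa * fm <= 0:
                    b = m
                else:
                    a, fa = m, fm
            return 0.5 * (a + b)
    return float(grid[best_idx])


def calibrate(cohort: Cohort, tolerance: float = 1e-4) -> ScalingConfig:
    """Full calibration: overall and per-sex sf, then the csf offset x
    (fitted with the overall sf).  Sex groups without enough records fall
    back to the overall factor."""
    records = _as_records(cohort)
    sf_overall = calibrate_sf(records, "all")
    try:
        sf_male = calibrate_sf(records, "male")
    except InputError:
        sf_male = sf_overall
    try:
        sf_female = calibrate_sf(records, "female")
    except InputError:
        sf_female = sf_overall
    has_lengths = all(r.scan_length is not None and r.body_length is not None for r in records)
    if has_lengths:
        offset_x = calibrate_offset_x(records, sf_overall, tolerance=tolerance)
    else:
        offset_x = ScalingConfig().offset_x
    return ScalingConfig(
        sf_overall=sf_overall, sf_male=sf_male, sf_female=sf_female, offset_x=offset_x
    )


def estimate_total_weight(
    record: CohortRecord,
    config: ScalingConfig,
    method: str = "sf",
    sex_specific: bool = True,
) -> float:
    """Extrapolate one subject's torso mass to whole-body weight.

    ``method="sf"`` divides by the (sex-specific when known) scaling
    factor; ``method="csf"`` first corrects it with the subject's relative
    scan length, which requires scan_length and body_length.
    """
    if method not in ("sf", "csf"):
        raise InputError(f"method must be sf or csf, got {method!r}")
    sf = config.sf_for(record.sex, sex_specific=sex_specific)
    if method == "sf":
        return extrapolate_sf(record.torso_weight, sf)
    if record.scan_length is None or record.body_length is None:
        raise InputError("csf method requires scan_length and body_length")
    csf = corrected_scaling_factor(sf, record.scan_length, record.body_length, config.offset_x)
    return extrapolate_sf(record.torso_weight, csf)
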