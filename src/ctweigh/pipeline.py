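"""End-to-end orchestration: read series → remove table → segment → weigh →
(optionally) extrapolate torso mass to whole-body weight."""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from typing import Optional

from .errors import CTWeighError, InputError
from .extrapolation import (
    CohortRecord,
    ScalingConfig,
    estimate_total_weight,
    scan_length_from_volume,
)
from .table_removal import TableRemovalConfig, fits_to_rows, remove_table
from .tissue_weight import TissueClassConfig, classify_voxels, estimate_weight
from .volume_io import CTVolume, SubjectMeta, read_dicom_series, read_nifti_volume

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Bundle of every stage's configuration plus orchestration switches."""

    tissue: TissueClassConfig = field(default_factory=TissueClassConfig)
    table: TableRemovalConfig = field(default_factory=TableRemovalConfig)
    scaling: ScalingConfig = field(default_factory=ScalingConfig)
    remove_table: bool = True
    extrapolation_method: str = "sf"  # "sf" | "csf"
    sex_specific: bool = True

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _load_volume(series_path) -> CTVolume:
    from pathlib import Path

    path = Path(series_path)
    if path.is_dir():
        return read_dicom_series(path)
    if path.suffix in (".nii", ".gz") or str(path).endswith(".nii.gz"):
        return read_nifti_volume(path)
    raise InputError(f"cannot interpret input {path}: not a directory or NIfTI file")


def run_pipeline(
    series_path,
    config: Optional[PipelineConfig] = None,
    mode: str = "whole_body",
    subject: Optional[SubjectMeta] = None,
) -> dict:
    """Run the full weight-estimation pipeline on one series.

    ``mode="whole_body"`` reports the summed tissue mass directly;
    ``mode="torso"`` additionally extrapolates it to whole-body weight
    with the configured scaling factors (the csf method needs the
    subject's body length).  The returned report always carries a
    ``status`` field; failures set ``status="error"`` instead of raising.
    """
    config = config or PipelineConfig()
    if mode not in ("whole_body", "torso"):
        raise InputError(f"mode must be whole_body or torso, got {mode!r}")
    report: dict = {
        "status": "ok",
        "mode": mode,
        "input": str(series_path),
        "config_hash": config.config_hash(),
        "warnings": [],
    }
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            volume = _load_volume(series_path)
            report["geometry"] = {
                "slice_count": volume.slice_count,
                "pixel_spacing_row_mm": volume.pixel_spacing_row,
                "pixel_spacing_col_mm": volume.pixel_spacing_col,
                "slice_thickness_mm": volume.slice_thickness,
                "slice_spacing_mm": volume.slice_spacing,
            }

            if config.remove_table:
                volume, fits = remove_table(volume, config.table)
                valid = sum(f.valid for f in fits)
                report["table_removal"] = {
                    "slices_fitted": valid,
                    "slices_total": len(fits),
                    "fits": fits_to_rows(fits),
                }
            else:
                report["table_removal"] = None

            masks = classify_voxels(volume, config.tissue)
            estimate = estimate_weight(masks, volume, config.tissue)
            report["weight"] = estimate.as_dict()

            if mode == "torso":
                subject = subject or volume.subject_meta or SubjectMeta()
                scan_length = scan_length_from_volume(volume)
                record_kwargs = dict(
                    subject_id="subject",
                    sex=subject.sex,
                    torso_weight=estimate.total_mass,
                    reference_weight=subject.reference_weight_kg or 1.0,
                    scan_length=scan_length,
                    body_length=subject.body_length_cm,
                )
                if config.extrapolation_method == "csf" and subject.body_length_cm is None:
                    raise InputError("csf extrapolation requires the subject's body length")
                record = CohortRecord(**record_kwargs)
                total = estimate_total_weight(
                    record,
                    config.scaling,
                    method=config.extrapolation_method,
                    sex_specific=config.sex_specific,
                )
                report["extrapolation"] = {
                    "method": config.extrapolation_method,
                    "sex": subject.sex,
                    "scan_length_cm": scan_length,
                    "body_length_cm": subject.body_length_cm,
                    "torso_mass_kg": estimate.total_mass,
                    "total_weight_kg": total,
                }
            report["warnings"] = [str(w.message) for w in caught]
    except (CTWeighError, OSError) as exc:
        report["status"] = "error"
        report["error"] = f"{type(exc).__name__}: {exc}"
        logger.error("pipeline failed: %s", exc)
    return report
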