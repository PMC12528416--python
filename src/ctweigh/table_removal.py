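"""Automatic removal of the patient table from axial CT slices.

The table (couch) is a thin dense band below the body.  Per slice:

1. vertical intensity profiles are taken at fixed fractions of the image
   width (default 25%, 50%, 75%),
2. each profile is Gaussian-smoothed,
3. the table's top edge is found in each profile as the lowest contiguous
   above-air band of plausible physical height that is separated from any
   tissue above it by an air run,
4. a quadratic curve is least-squares fitted through the (column, top row)
   edge points,
5. everything at and below the curve is replaced with air (-1000 HU) —
   the whole sub-table region, since nothing below the table top can be
   body.

Because edge rows are integers, the fitted parabola can drift from the
true table top by a few rows when evaluated far from the profile columns.
The cut row for each column is therefore snapped to the nearest air-to-
table transition within a small window around the fitted curve
(``snap_window_voxels``, 0 disables), which keeps removal voxel-exact
while the quadratic still isolates the region.

Slices where no table is detected fall back to the volume-median curve
when at least half of the slices fitted; otherwise they are left
unmodified.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .errors import InputError, TableRemovalWarning
from .volume_io import CTVolume

AIR_HU = -1000.0


@dataclass(frozen=True)
class TableRemovalConfig:
    """Tunable parameters of the table-removal stage.

    fractions
        Relative image-width positions of the profile lines.
    smoothing_sigma
        Gaussian sigma in voxels for profile smoothing.
    air_threshold_hu
        Values above this count as "not air" during edge detection.
    min_band_mm, max_band_mm
        Physical height bounds a candidate table band must satisfy.
    min_gap_voxels
        Required air run immediately above the band (separation from body).
    snap_window_voxels
        Half-width of the per-column refinement window around the fitted
        curve; 0 uses the raw fitted curve.
    """

    fractions: Tuple[float, ...] = (0.25, 0.50, 0.75)
    smoothing_sigma: float = 2.0
    air_threshold_hu: float = -500.0
    min_band_mm: float = 5.0
    max_band_mm: float = 60.0
    min_gap_voxels: int = 3
    snap_window_voxels: int = 5


@dataclass
class TableFit:
    """Per-slice quadratic fit of the table's top edge.

    ``coefficients`` are (a, b, c) of top_row = a·col² + b·col + c; the fit
    is valid when at least three distinct-column edge points exist and all
    residuals are within 2 rows.
    """

    slice_index: int
    edge_points: List[Tuple[int, int]] = field(default_factory=list)
    coefficients: Optional[Tuple[float, float, float]] = None
    valid: bool = False

    def evaluate(self, col) -> np.ndarray:
        if self.coefficients is None:
            raise InputError("fit has no coefficients")
        a, b, c = self.coefficients
        col = np.asarray(col, dtype=float)
        return a * col**2 + b * col + c


def extract_profiles(
    slice_image: np.ndarray,
    fractions: Sequence[float] = (0.25, 0.50, 0.75),
) -> List[Tuple[int, np.ndarray]]:
    """Vertical intensity profiles at fixed fractions of the image width.

    Returns ``[(column_index, profile), ...]`` with the profile running
    top row to bottom row.  Column index is ``round(f · (n_cols − 1))``;
    duplicate columns after rounding are collapsed, and extra fractions at
    ±0.05 steps are tried until three distinct columns are available.
    """
    slice_image = np.asarray(slice_image)
    if slice_image.ndim != 2:
        raise InputError("expected a 2-D slice")
    n_cols = slice_image.shape[1]
    if n_cols < 4:
        raise InputError(f"slice narrower than 4 columns ({n_cols})")

    candidates = list(fractions)
    for k in range(1, 5):
        for f in fractions:
            for sign in (-1, 1):
                g = f + sign * 0.05 * k
                if 0.0 < g < 1.0:
                    candidates.append(g)

    columns: List[int] = []
    for idx, f in enumerate(candidates):
        col = int(round(f * (n_cols - 1)))
        if col not in columns:
            columns.append(col)
        if idx >= len(fractions) - 1 and len(columns) >= 3:
            break
    columns = columns if len(columns) <= 3 else columns[: max(3, len(fractions))]
    return [(col, slice_image[:, col].astype(np.float64)) for col in sorted(columns)]


def smooth_profile(profile: np.ndarray, sigma_voxels: float) -> np.ndarray:
    """Gaussian-smooth a 1-D profile with reflective boundaries."""
    profile = np.asarray(profile, dtype=np.float64)
    if profile.ndim != 1 or profile.size < 3:
        raise InputError("profile must be 1-D with length >= 3")
    if not sigma_voxels > 0:
        raise InputError("sigma_voxels must be > 0")
    return ndimage.gaussian_filter1d(profile, sigma_voxels, mode="reflect")


def detect_table_edges(
    smoothed_profile: np.ndarray,
    air_threshold_hu: float = -500.0,
    min_band_mm: float = 5.0,
    max_band_mm: float = 60.0,
    pixel_spacing_row: float = 1.0,
    min_gap_voxels: int = 3,
) -> Optional[Tuple[int, int]]:
    """Locate the table band in one smoothed profile.

    Scans above-air runs from the bottom of the profile upward.  A run
    whose physical height lies in [min_band_mm, max_band_mm] and whose
    ``min_gap_voxels`` rows immediately above are all air qualifies as the
    table; its (top_row, bottom_row) is returned.  A run taller than
    ``max_band_mm`` is body (possibly body merged with table) and stops
    the search; runs shorter than ``min_band_mm`` are skipped as debris.
    ``None`` signals "no table" — a valid outcome, not an error.
    """
    profile = np.asarray(smoothed_profile, dtype=np.float64)
    above = profile > air_threshold_hu
    if not above.any():
        return None
    # contiguous runs of above-air rows
    padded = np.diff(np.concatenate(([0], above.view(np.int8), [0])))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1) - 1
    for s, e in zip(starts[::-1], ends[::-1]):
        height_mm = (e - s + 1) * pixel_spacing_row
        if height_mm > max_band_mm:
            return None
        if height_mm < min_band_mm:
            continue
        if s < min_gap_voxels:
            return None  # band touches the top of the image: no air above
        if above[s - min_gap_voxels : s].any():
            return None  # insufficient air gap to the structure above
        return int(s), int(e)
    return None


def fit_table_curve(
    edge_points: Sequence[Tuple[int, int]],
    slice_index: int = -1,
) -> TableFit:
    """Least-squares quadratic through (column, top_row) edge points.

    With exactly three distinct columns the fit interpolates.  Fewer than
    three points, duplicate columns, or residuals above 2 rows mark the
    fit invalid — no exception is raised.
    """
    points = sorted(edge_points)
    fit = TableFit(slice_index=slice_index, edge_points=[(int(c), int(r)) for c, r in points])
    cols = np.array([c for c, _ in points], dtype=float)
    rows = np.array([r for _, r in points], dtype=float)
    if len(points) < 3 or len(np.unique(cols)) < len(cols):
        return fit
    a, b, c = np.polyfit(cols, rows, 2)
    fit.coefficients = (float(a), float(b), float(c))
    residuals = np.abs(fit.evaluate(cols) - rows)
    fit.valid = bool(np.all(residuals <= 2.0))
    return fit


def _snap_cut_row(
    raw_column: np.ndarray,
    fitted_row: float,
    air_threshold_hu: float,
    window: int,
) -> int:
    """Refine a column's cut row to the nearest air-to-table transition.

    A transition row r satisfies profile[r] > air and profile[r-1] <= air.
    Search is limited to ±window rows around the fitted curve; absent any
    transition the (ceiled) fitted row is kept.
    """
    n = raw_column.size
    base = int(np.ceil(fitted_row - 1e-9))
    if window <= 0:
        return base
    lo = max(1, int(round(fitted_row)) - window)
    hi = min(n - 1, int(round(fitted_row)) + window)
    best = None
    for r in range(lo, hi + 1):
        if raw_column[r] > air_threshold_hu and raw_column[r - 1] <= air_threshold_hu:
            if best is None or abs(r - fitted_row) < abs(best - fitted_row):
                best = r
    return best if best is not None else base


def _apply_curve(
    slice_hu: np.ndarray,
    coefficients: Tuple[float, float, float],
    config: TableRemovalConfig,
) -> None:
    """In-place: set everything at and below the table-top curve to air."""
    a, b, c = coefficients
    n_rows, n_cols = slice_hu.shape
    for j in range(n_cols):
        fitted = a * j * j + b * j + c
        cut = _snap_cut_row(slice_hu[:, j], fitted, config.air_threshold_hu, config.snap_window_voxels)
        cut = max(0, min(cut, n_rows))
        slice_hu[cut:, j] = AIR_HU


def fit_slice_table(
    slice_hu: np.ndarray,
    pixel_spacing_row: float,
    config: TableRemovalConfig,
    slice_index: int = -1,
) -> TableFit:
    """Run profile extraction, smoothing, edge detection and curve fitting
    for a single slice."""
    edges = []
    for col, profile in extract_profiles(slice_hu, config.fractions):
        smoothed = smooth_profile(profile, config.smoothing_sigma)
        band = detect_table_edges(
            smoothed,
            air_threshold_hu=config.air_threshold_hu,
            min_band_mm=config.min_band_mm,
            max_band_mm=config.max_band_mm,
            pixel_spacing_row=pixel_spacing_row,
            min_gap_voxels=config.min_gap_voxels,
        )
        if band is not None:
            edges.append((col, band[0]))
    return fit_table_curve(edges, slice_index=slice_index)


def remove_table(
    volume: CTVolume,
    config: Optional[TableRemovalConfig] = None,
) -> Tuple[CTVolume, List[TableFit]]:
    """Remove the patient table from every slice of a volume.

    Returns a modified copy (the input is untouched) and the per-slice
    fits.  Slices with invalid fits reuse the volume-median coefficients
    when at least 50% of slices fitted; with fewer valid fits they are
    left unmodified (a warning is emitted if some — but not enough —
    slices did fit).  A volume with no detectable table anywhere passes
    through bit-identical.
    """
    config = config or TableRemovalConfig()
    out = volume.copy()
    fits = [
        fit_slice_table(out.voxels[k], out.pixel_spacing_row, config, slice_index=k)
        for k in range(out.slice_count)
    ]
    valid = [f for f in fits if f.valid]
    fallback: Optional[Tuple[float, float, float]] = None
    if valid and len(valid) >= 0.5 * len(fits):
        coeffs = np.array([f.coefficients for f in valid], dtype=float)
        fallback = tuple(np.median(coeffs, axis=0))
    elif 0 < len(valid) < len(fits):
        warnings.warn(
            f"table fitted on only {len(valid)}/{len(fits)} slices (<50%); "
            "unfitted slices left unmodified",
            TableRemovalWarning,
            stacklevel=2,
        )
    for fit in fits:
        if fit.valid and fit.coefficients is not None:
            _apply_curve(out.voxels[fit.slice_index], fit.coefficients, config)
        elif fallback is not None:
            _apply_curve(out.voxels[fit.slice_index], fallback, config)
    return out, fits


def fits_to_rows(fits: Sequence[TableFit]) -> List[dict]:
    """CSV-ready rows (slice_index, a, b, c, valid) for a fit report."""
    rows = []
    for f in fits:
        a, b, c = f.coefficients if f.coefficients is not None else (np.nan, np.nan, np.nan)
        rows.append(
            {"slice_index": f.slice_index, "a": a, "b": b, "c": c, "valid": f.valid}
        )
    return rows
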