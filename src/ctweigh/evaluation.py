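"""Agreement statistics between estimated and reference body weights.

Sign convention: difference = estimate − reference.  "Median relative
deviation" is the median of *signed* percentage deviations; "mean relative
error" is the mean of *absolute* percentage errors.  R² comes from the
ordinary least-squares regression of estimate on reference (identical to
the squared Pearson correlation in simple regression).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
from scipy import stats

from .errors import InputError


@dataclass(frozen=True)
class EvaluationSummary:
    """Cohort-level agreement between estimates and references."""

    n: int
    mean_diff: float  # kg, estimate − reference
    sd_diff: float  # kg
    median_diff: float  # kg
    abs_mean_diff: float  # kg
    abs_sd_diff: float  # kg
    abs_median_diff: float  # kg
    r_squared: float
    median_rel_dev_pct: float  # median of signed % deviations
    mean_rel_err_pct: float  # mean of absolute % errors
    sd_rel_err_pct: float
    correlations: Optional[Dict[str, Optional[float]]] = None

    def as_dict(self) -> dict:
        d = {
            "n": self.n,
            "mean_diff_kg": self.mean_diff,
            "sd_diff_kg": self.sd_diff,
            "median_diff_kg": self.median_diff,
            "abs_mean_diff_kg": self.abs_mean_diff,
            "abs_sd_diff_kg": self.abs_sd_diff,
            "abs_median_diff_kg": self.abs_median_diff,
            "r_squared": self.r_squared,
            "median_rel_dev_pct": self.median_rel_dev_pct,
            "mean_rel_err_pct": self.mean_rel_err_pct,
            "sd_rel_err_pct": self.sd_rel_err_pct,
        }
        if self.correlations is not None:
            d["correlations"] = dict(self.correlations)
        return d


def agreement_stats(
    estimates: Sequence[float],
    references: Sequence[float],
) -> EvaluationSummary:
    """Summary statistics of estimate-vs-reference agreement.

    diff_i = estimate_i − reference_i; relative deviation (signed) and
    relative error (absolute) are percentages of the reference.
    """
    est = np.asarray(estimates, dtype=float)
    ref = np.asarray(references, dtype=float)
    if est.shape != ref.shape or est.ndim != 1:
        raise InputError("estimates and references must be equal-length 1-D sequences")
    n = est.size
    if n < 2:
        raise InputError("need at least 2 pairs")
    if np.any(ref <= 0):
        raise InputError("references must be > 0")

    diff = est - ref
    rel_dev = diff / ref * 100.0
    rel_err = np.abs(rel_dev)

    if np.allclose(est, ref):
        r_squared = 1.0  # perfect agreement, regardless of reference spread
    elif np.ptp(ref) == 0 or np.ptp(est) == 0:
        r_squared = float("nan")
    else:
        fit = stats.linregress(ref, est)
        r_squared = float(fit.rvalue**2)

    return EvaluationSummary(
        n=int(n),
        mean_diff=float(diff.mean()),
        sd_diff=float(diff.std(ddof=1)),
        median_diff=float(np.median(diff)),
        abs_mean_diff=float(np.abs(diff).mean()),
        abs_sd_diff=float(np.abs(diff).std(ddof=1)),
        abs_median_diff=float(np.median(np.abs(diff))),
        r_squared=r_squared,
        median_rel_dev_pct=float(np.median(rel_dev)),
        mean_rel_err_pct=float(rel_err.mean()),
        sd_rel_err_pct=float(rel_err.std(ddof=1)),
    )


def error_composition_correlations(
    rel_errors: Sequence[float],
    covariates: Dict[str, Sequence[float]],
) -> Dict[str, Optional[float]]:
    """Pearson r of the relative error against per-subject covariates
    (typically body weight and fat/muscle/bone volumes).

    A zero-variance covariate (or zero-variance error) yields ``None`` —
    the correlation is undefined there, not zero.
    """
    err = np.asarray(rel_errors, dtype=float)
    if err.size < 3:
        raise InputError("need at least 3 subjects for correlations")
    out: Dict[str, Optional[float]] = {}
    for name, values in covariates.items():
        v = np.asarray(values, dtype=float)
        if v.shape != err.shape:
            raise InputError(f"covariate {name!r} length mismatch")
        if np.ptp(v) == 0 or np.ptp(err) == 0:
            out[name] = None
        else:
            out[name] = float(stats.pearsonr(err, v).statistic)
    return out
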