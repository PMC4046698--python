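"""Calibration of raw PRT ratios against reference samples, and empirical
error-model estimation.

A PRT yields a raw test:reference peak-area ratio that is proportional to,
but not equal to, the diploid gene copy number.  Reference samples of known
integer copy number (originally anchored by pulsed-field gel typing) are used
to fit an affine map raw -> copies by ordinary least squares.  The intercept
is retained rather than forcing the fit through the origin: the MLT1A0 PRT
amplifies only full 19 kb repeats and so measures one copy less per haplotype
than the other assays, yet by convention it is calibrated directly to the
total repeat-unit count per sample so that all five measurements share a
common scale.

Once a cohort has been called, the per-assay error model is re-estimated from
the spread of normalised measurements (measurement / assigned integer), whose
standard deviation is the relative SD used by the Gaussian likelihoods.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from scipy import stats

from .models import InsufficientDataError, normalise_measurement

__all__ = [
    "CalibrationFit",
    "OutlierReport",
    "fit_prt_calibration",
    "estimate_error_model",
]


class DegenerateFitError(InsufficientDataError):
    """All reference samples share one copy number; no slope can be fitted."""


@dataclass(frozen=True)
class CalibrationFit:
    """Affine map from raw PRT ratio to unrounded copy-number estimate."""

    assay: str
    slope: float
    intercept: float
    residual_sd: float
    reference_ids: Tuple[str, ...] = ()

    def __call__(self, raw) -> np.ndarray:
        """Apply the calibration: copies = slope * raw + intercept."""
        return self.slope * np.asarray(raw, dtype=float) + self.intercept


def fit_prt_calibration(
    pairs: Sequence[Tuple[float, float]],
    assay: str = "PRT",
    reference_ids: Sequence[str] = (),
) -> CalibrationFit:
    """Least-squares affine calibration raw ratio -> integer copy number.

    Parameters
    ----------
    pairs
        Sequence of (raw ratio, known integer copy number) for reference
        samples; at least two distinct known copy numbers are required.

    Returns
    -------
    CalibrationFit
        With copies as the response variable, so that predicted copy numbers
        come directly from ``fit(raw)``.  Rounding to integers is never done
        here; integer assignment is the caller's job.
    """
    if len(pairs) < 2:
        raise InsufficientDataError("need at least two reference samples")
    raw = np.array([p[0] for p in pairs], dtype=float)
    copies = np.array([p[1] for p in pairs], dtype=float)
    if len(set(copies.tolist())) < 2:
        raise DegenerateFitError(
            "all reference samples share one copy number; slope is undetermined"
        )
    if len(set(raw.tolist())) < 2:
        raise DegenerateFitError("all raw ratios identical; slope is undetermined")
    res = stats.linregress(raw, copies)
    fitted = res.slope * raw + res.intercept
    dof = max(len(pairs) - 2, 1)
    residual_sd = float(np.sqrt(np.sum((copies - fitted) ** 2) / dof))
    return CalibrationFit(
        assay=assay,
        slope=float(res.slope),
        intercept=float(res.intercept),
        residual_sd=residual_sd,
        reference_ids=tuple(reference_ids),
    )


@dataclass(frozen=True)
class OutlierReport:
    """Counts of |z| > 2 outliers among normalised measurements.

    Under the Gaussian error model about 2.3% of measurements are expected on
    each side of |z| = 2; an excess on the low side has been observed
    empirically for the MLT1A0 PRT and is worth monitoring.
    """

    n: int
    n_low: int  # z < -2
    n_high: int  # z > 2
    expected_each_side: float

    @property
    def low_excess(self) -> float:
        return self.n_low - self.expected_each_side

    @property
    def high_excess(self) -> float:
        return self.n_high - self.expected_each_side


def estimate_error_model(
    calls: Sequence[Tuple[float, int]], assay: str = "PRT"
) -> Tuple[float, OutlierReport]:
    """Empirical relative SD of an assay from called samples.

    Parameters
    ----------
    calls
        Sequence of (measurement, assigned integer copy number) pairs; at
        least 10 are required for a meaningful estimate.

    Returns
    -------
    (sigma_rel, report)
        ``sigma_rel`` is the standard deviation of the normalised
        measurements m/N (ddof=1); the report tallies outliers beyond
        |z| = 2 against the two-sided Gaussian expectation.
    """
    if len(calls) < 10:
        raise InsufficientDataError(
            f"need at least 10 calls to estimate an error model, got {len(calls)}"
        )
    norm = np.array([normalise_measurement(m, n) for m, n in calls])
    sigma_rel = float(np.std(norm, ddof=1))
    if sigma_rel > 0:
        z = (norm - 1.0) / sigma_rel
        n_low = int(np.sum(z < -2))
        n_high = int(np.sum(z > 2))
    else:
        n_low = n_high = 0
    expected = float(len(calls) * stats.norm.sf(2.0))
    return sigma_rel, OutlierReport(
        n=len(calls), n_low=n_low, n_high=n_high, expected_each_side=expected
    )
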