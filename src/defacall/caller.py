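"""Combining assay evidence into integer copy-number calls.

Per-assay relative-likelihood rows are combined by multiplication: under
independent measurement errors the joint likelihood of the five measurements
at a candidate copy number N is the product of the per-assay likelihoods, so
the integer maximising the product maximises the joint probability of all the
data.  The called integer is the maximum-likelihood copy number (MLCN); the
minimum ratio (MR) — combined support at the MLCN divided by support at the
next-best integer — is the confidence index attached to each call.
"""

from __future__ import annotations

import math
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from .models import (
    DEFAULT_MODEL,
    PRT_ASSAYS,
    RATIO_ASSAYS,
    DefacallError,
    ErrorModel,
    InvalidMeasurementError,
    LikelihoodProfile,
    MeasurementPanel,
    RatioCall,
    compositions,
    expected_ratio,
    prt_relative_likelihoods,
    ratio_comparison,
    ratio_relative_likelihoods,
)

__all__ = [
    "combine_evidence",
    "call_mlcn",
    "qc_include",
    "flag_anomalies",
    "interpret_ratio",
    "call_sample",
    "call_cohort",
]

RowSet = Union[Mapping[str, np.ndarray], Sequence[np.ndarray]]


def _as_row_list(rows: RowSet) -> List[np.ndarray]:
    if isinstance(rows, Mapping):
        items = list(rows.values())
    else:
        items = list(rows)
    if not items:
        raise DefacallError("no likelihood rows to combine")
    lengths = {len(r) for r in items}
    if len(lengths) != 1:
        raise DefacallError(f"rows span different copy-number ranges: lengths {sorted(lengths)}")
    return [np.asarray(r, dtype=float) for r in items]


def combine_evidence(rows: RowSet, floor: float = 1e-308) -> np.ndarray:
    """Element-wise product of relative-likelihood rows, rescaled to max 1.

    Values below ``floor`` after rescaling are rounded to exactly 0.  A single
    row is returned unchanged (up to rescaling), the multiplicative identity.
    """
    items = _as_row_list(rows)
    with np.errstate(under="ignore"):
        combined = np.prod(items, axis=0)
    top = combined.max()
    if top <= 0:
        raise DefacallError("combined likelihood is zero everywhere (irreconcilable rows)")
    combined = combined / top
    combined[combined < floor] = 0.0
    return combined


def call_mlcn(
    combined: np.ndarray, copy_numbers: Optional[np.ndarray] = None
) -> Tuple[int, float, bool]:
    """MLCN and minimum ratio from a combined relative-likelihood row.

    Returns ``(mlcn, mr, tie)``.  The MLCN is the copy number with the largest
    combined value; MR is the best value divided by the second-best value
    anywhere else in the row (MR >= 1; MR = 1 for an exact tie or a flat row,
    flagged via ``tie``).  An exact tie at the maximum is resolved to the
    smaller copy number.
    """
    combined = np.asarray(combined, dtype=float)
    if copy_numbers is None:
        copy_numbers = np.arange(2, 2 + len(combined))
    if len(copy_numbers) != len(combined):
        raise DefacallError("combined row and copy-number grid differ in length")
    best_idx = int(np.argmax(combined))  # argmax takes the first (smaller N) on ties
    best = combined[best_idx]
    if best <= 0:
        raise DefacallError("combined row has no positive support")
    rest = np.delete(combined, best_idx)
    second = float(rest.max()) if len(rest) else 0.0
    if second <= 0:
        mr = math.inf
        tie = False
    else:
        mr = float(best / second)
        tie = math.isclose(mr, 1.0, rel_tol=0.0, abs_tol=1e-12)
    return int(copy_numbers[best_idx]), mr, tie


def qc_include(panel: MeasurementPanel) -> bool:
    """Inclusion rule: at least two present measurements, at least one a PRT."""
    return panel.n_present >= 2 and panel.n_present_prt >= 1


def flag_anomalies(
    rows: Mapping[str, np.ndarray],
    mlcn: int,
    model: ErrorModel = DEFAULT_MODEL,
    present: Optional[Iterable[str]] = None,
) -> List[str]:
    """Assays whose relative likelihood at the called copy number is very low.

    A measurement with relative likelihood below ``model.anomaly_threshold``
    (default 5e-4) at the MLCN contradicts the assumption that the same
    underlying copy number applies to all measured sequence elements, and is
    flagged for manual review.  Missing assays (all-ones rows) never flag.
    """
    idx = np.nonzero(model.copy_numbers == mlcn)[0]
    if len(idx) == 0:
        raise DefacallError(f"MLCN {mlcn} outside model range {model.n_min}..{model.n_max}")
    i = idx[0]
    names = list(rows) if present is None else [a for a in rows if a in set(present)]
    return [a for a in names if rows[a][i] < model.anomaly_threshold]


def interpret_ratio(
    r: float, n: int, assay: str, model: ErrorModel = DEFAULT_MODEL
) -> RatioCall:
    """Best integer interpretation a:b of an observed ratio given total n.

    Exhaustively scores all n - 1 compositions (a, b) with a + b = n and
    a, b >= 1, and returns the one whose expected ratio k*a/b is closest to r
    under the configured comparison metric.  This is the per-assay integer
    interpretation derived from the MLCN.
    """
    if n < 2:
        raise InvalidMeasurementError(f"no two-class composition exists for total {n}")
    if not math.isfinite(r) or r <= 0:
        raise InvalidMeasurementError(f"ratio must be > 0, got {r!r}")
    k = model.k.get(assay, 1.0)
    best = min(
        compositions(n),
        key=lambda ab: abs(ratio_comparison(r, expected_ratio(*ab, k), model.ratio_metric)),
    )
    return RatioCall(assay=assay, a=best[0], b=best[1])


def call_sample(panel: MeasurementPanel, model: ErrorModel = DEFAULT_MODEL) -> LikelihoodProfile:
    """Full calling pipeline for one sample.

    Builds the five per-assay relative-likelihood rows (all-ones where
    missing), combines them by multiplication, extracts MLCN and MR, flags
    anomalous assays, applies the inclusion rule and attaches the best integer
    interpretation of each present ratio at the MLCN.
    """
    rows: Dict[str, np.ndarray] = {}
    for assay in PRT_ASSAYS:
        rows[assay] = prt_relative_likelihoods(panel.value(assay), assay, model)
    for assay in RATIO_ASSAYS:
        rows[assay] = ratio_relative_likelihoods(panel.value(assay), assay, model)

    combined = combine_evidence(rows, floor=model.underflow_floor)
    mlcn, mr, tie = call_mlcn(combined, model.copy_numbers)
    anomalies = flag_anomalies(rows, mlcn, model, present=panel.present_assays)

    ratio_calls: Dict[str, RatioCall] = {}
    for assay in RATIO_ASSAYS:
        r = panel.value(assay)
        if r is not None:
            ratio_calls[assay] = interpret_ratio(r, mlcn, assay, model)

    return LikelihoodProfile(
        sample_id=panel.sample_id,
        copy_numbers=model.copy_numbers.copy(),
        rows=rows,
        combined=combined,
        mlcn=mlcn,
        mr=mr,
        anomalies=anomalies,
        included=qc_include(panel),
        tie=tie,
        ratio_calls=ratio_calls,
    )


def call_cohort(
    panels: Iterable[MeasurementPanel], model: ErrorModel = DEFAULT_MODEL
) -> List[LikelihoodProfile]:
    """Call every sample in a cohort; excluded samples keep their profile but
    carry ``included=False``."""
    return [call_sample(p, model) for p in panels]
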