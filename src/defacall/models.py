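"""Core domain types and per-assay likelihood models for DEFA1A3 copy-number calling.

The DEFA1A3 alpha-defensin locus on chromosome 8 is a multi-allelic CNV in
which each haplotype carries a variable number of 19 kb repeat units, each
occupied by either a *DEFA1* or a *DEFA3* gene.  Diploid gene copy number is
measured here by five independent assays:

* two paralogue ratio tests (PRTs), ``MLT1A0`` and ``DEFA4``, each yielding an
  unrounded (calibrated) copy-number estimate, and
* three allelic-ratio assays quantifying the peak-area ratio between two
  sequence variants of the repeat: ``indel5`` (deleted : undeleted),
  ``DefHae3`` (DEFA1 : DEFA3) and ``7bpdup`` (unduplicated : duplicated).

Each measurement is turned into a row of *relative likelihoods* over candidate
integer copy numbers N (default 2..16).  PRT measurements are modelled as
Gaussian around the true copy number with a standard deviation proportional to
N, because the empirical error of these assays is multiplicative: the spread
of *normalised* measurements (measurement divided by true copy number) is what
is constant across copy-number classes.  An allelic ratio r constrains the
integer composition (a, b) with a + b = N: the expected ratio for a
composition is k * a / b (k a per-assay calibration constant), and the row
value at N is the best Gaussian kernel over all compositions compatible with
N.  Rows are rescaled so their maximum over the copy-number range is exactly
1; a missing measurement contributes an uninformative all-ones row.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np

__all__ = [
    "PRT_ASSAYS",
    "RATIO_ASSAYS",
    "ALL_ASSAYS",
    "DefacallError",
    "InvalidMeasurementError",
    "ConfigurationError",
    "InsufficientDataError",
    "MeasurementPanel",
    "ErrorModel",
    "RatioCall",
    "LikelihoodProfile",
    "compositions",
    "expected_ratio",
    "ratio_comparison",
    "prt_relative_likelihoods",
    "ratio_relative_likelihoods",
    "normalise_measurement",
    "normalised_z",
]

#: Paralogue ratio test assays, in panel column order.
PRT_ASSAYS: Tuple[str, ...] = ("MLT1A0", "DEFA4")

#: Allelic-ratio assays, in panel column order.
RATIO_ASSAYS: Tuple[str, ...] = ("indel5", "DefHae3", "7bpdup")

#: All five assays, in panel column order.
ALL_ASSAYS: Tuple[str, ...] = PRT_ASSAYS + RATIO_ASSAYS


class DefacallError(Exception):
    """Base class for errors raised by this package."""


class InvalidMeasurementError(DefacallError, ValueError):
    """A measurement value is outside its valid domain (e.g. negative)."""


class ConfigurationError(DefacallError, ValueError):
    """An assay name or model parameter is not recognised or not valid."""


class InsufficientDataError(DefacallError, ValueError):
    """Too few observations to carry out the requested estimate."""


# ---------------------------------------------------------------------------
# Measurement panel
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MeasurementPanel:
    """One sample's five raw measurements.

    ``None`` encodes a missing/uninformative measurement.  In the source data
    convention a recorded value of 0 is a catch-all indicator of absent
    information (no result, or a single-peak ratio), never a measured copy
    number of zero; use :meth:`from_values` to apply that convention.
    All present values must be strictly positive.
    """

    sample_id: str
    prt_mlt1a0: Optional[float] = None
    prt_defa4: Optional[float] = None
    ratio_indel5: Optional[float] = None
    ratio_defhae3: Optional[float] = None
    ratio_7bpdup: Optional[float] = None

    _FIELD_BY_ASSAY = {
        "MLT1A0": "prt_mlt1a0",
        "DEFA4": "prt_defa4",
        "indel5": "ratio_indel5",
        "DefHae3": "ratio_defhae3",
        "7bpdup": "ratio_7bpdup",
    }

    def __post_init__(self) -> None:
        for assay, name in self._FIELD_BY_ASSAY.items():
            v = getattr(self, name)
            if v is None:
                continue
            if not math.isfinite(v) or v <= 0:
                raise InvalidMeasurementError(
                    f"{self.sample_id}: {assay} measurement must be a positive "
                    f"number or missing, got {v!r}"
                )

    @classmethod
    def from_values(cls, sample_id: str, values: Mapping[str, float]) -> "MeasurementPanel":
        """Build a panel from raw per-assay values, mapping 0/NaN to missing."""
        kwargs = {}
        for assay, name in cls._FIELD_BY_ASSAY.items():
            v = values.get(assay)
            if v is None or (isinstance(v, float) and math.isnan(v)) or v == 0:
                kwargs[name] = None
            elif v < 0:
                raise InvalidMeasurementError(
                    f"{sample_id}: negative value {v!r} for {assay}"
                )
            else:
                kwargs[name] = float(v)
        return cls(sample_id=sample_id, **kwargs)

    def value(self, assay: str) -> Optional[float]:
        try:
            return getattr(self, self._FIELD_BY_ASSAY[assay])
        except KeyError:
            raise ConfigurationError(f"unknown assay {assay!r}") from None

    def values(self) -> Dict[str, Optional[float]]:
        return {assay: self.value(assay) for assay in ALL_ASSAYS}

    @property
    def present_assays(self) -> Tuple[str, ...]:
        return tuple(a for a in ALL_ASSAYS if self.value(a) is not None)

    @property
    def n_present(self) -> int:
        return len(self.present_assays)

    @property
    def n_present_prt(self) -> int:
        return sum(1 for a in PRT_ASSAYS if self.value(a) is not None)


# ---------------------------------------------------------------------------
# Error model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ErrorModel:
    """Measurement-error model and calling configuration.

    Parameters
    ----------
    n_min, n_max
        Inclusive range of candidate integer diploid copy numbers (2..16).
    sigma_rel
        Per-PRT relative standard deviation: the SD of the *normalised*
        measurement m/N.  The SD of the raw measurement at true copy number N
        is therefore ``sigma_rel * N``.  Defaults are the empirical values
        0.114 (MLT1A0) and 0.12 (DEFA4).
    sigma_ratio
        Per-ratio-assay SD of the ratio-comparison metric (see
        ``ratio_metric``); default 0.15 for all three assays.
    k
        Per-ratio-assay multiplicative calibration constant mapping an integer
        composition a:b to the expected observed peak-area ratio k*a/b.
        Default 1.0 (uncalibrated).
    ratio_metric
        ``"log"`` (default) compares log(r / expected), treating peak-area
        noise as multiplicative; ``"linear"`` compares r - expected.
    composition_mode
        ``"max"`` (default) scores a copy number by its best-fitting
        composition; ``"sum"`` marginalises over all compositions.
    anomaly_threshold
        Relative likelihood at the called copy number below which a
        measurement is flagged as anomalous (default 5e-4).
    underflow_floor
        Relative likelihoods below this are rounded to exactly 0 (default
        1e-308, the approximate double-precision underflow limit).
    """

    n_min: int = 2
    n_max: int = 16
    sigma_rel: Mapping[str, float] = field(
        default_factory=lambda: {"MLT1A0": 0.114, "DEFA4": 0.12}
    )
    sigma_ratio: Mapping[str, float] = field(
        default_factory=lambda: {a: 0.15 for a in RATIO_ASSAYS}
    )
    k: Mapping[str, float] = field(default_factory=lambda: {a: 1.0 for a in RATIO_ASSAYS})
    ratio_metric: str = "log"
    composition_mode: str = "max"
    anomaly_threshold: float = 5e-4
    underflow_floor: float = 1e-308

    def __post_init__(self) -> None:
        if self.n_min < 1:
            raise ConfigurationError("n_min must be >= 1")
        if self.n_max < self.n_min:
            raise ConfigurationError("n_max must be >= n_min")
        for name, table in (("sigma_rel", self.sigma_rel), ("sigma_ratio", self.sigma_ratio)):
            for assay, s in table.items():
                if s <= 0:
                    raise ConfigurationError(f"{name}[{assay}] must be > 0, got {s}")
        for assay, kk in self.k.items():
            if kk <= 0:
                raise ConfigurationError(f"k[{assay}] must be > 0, got {kk}")
        if self.ratio_metric not in ("log", "linear"):
            raise ConfigurationError(f"unknown ratio_metric {self.ratio_metric!r}")
        if self.composition_mode not in ("max", "sum"):
            raise ConfigurationError(f"unknown composition_mode {self.composition_mode!r}")
        if not 0 < self.anomaly_threshold < 1:
            raise ConfigurationError("anomaly_threshold must be in (0, 1)")
        if not 0 < self.underflow_floor < 1:
            raise ConfigurationError("underflow_floor must be in (0, 1)")

    @property
    def copy_numbers(self) -> np.ndarray:
        """Candidate integer copy numbers, n_min..n_max inclusive."""
        return np.arange(self.n_min, self.n_max + 1)

    def with_range(self, n_min: int, n_max: int) -> "ErrorModel":
        return replace(self, n_min=n_min, n_max=n_max)


#: Default model with the empirical PRT SDs and uncalibrated ratios.
DEFAULT_MODEL = ErrorModel()


# ---------------------------------------------------------------------------
# Ratio compositions
# ---------------------------------------------------------------------------


def compositions(n: int) -> List[Tuple[int, int]]:
    """All integer compositions (a, b) of n with a >= 1 and b >= 1.

    A measured two-peak ratio implies both variant classes are present, so
    single-class compositions (a=0 or b=0) are excluded; a single-peak
    observation arrives as a missing measurement instead.
    """
    return [(a, n - a) for a in range(1, n)]


def expected_ratio(a: int, b: int, k: float = 1.0) -> float:
    """Expected observed peak-area ratio for integer composition a:b."""
    if b == 0:
        raise InvalidMeasurementError("composition with b = 0 has no finite ratio")
    return k * a / b


def ratio_comparison(r: float, expected: float, metric: str = "log") -> float:
    """Comparison metric between an observed ratio and an expected ratio.

    ``"log"`` returns log(r/expected) (symmetric under orientation flips of
    the assay, since flipping both r and expected only changes the sign);
    ``"linear"`` returns r - expected.
    """
    if metric == "log":
        return math.log(r / expected)
    if metric == "linear":
        return r - expected
    raise ConfigurationError(f"unknown ratio metric {metric!r}")


# ---------------------------------------------------------------------------
# Per-assay relative-likelihood rows
# ---------------------------------------------------------------------------


def _finalise_row(dens: np.ndarray, floor: float) -> np.ndarray:
    """Rescale an unnormalised density row so its maximum is exactly 1."""
    top = dens.max()
    if top <= 0 or not np.isfinite(top):
        # Degenerate underflow of every candidate: no information retained.
        return np.ones_like(dens)
    row = dens / top
    row[row < floor] = 0.0
    return row


def prt_relative_likelihoods(
    m: Optional[float], assay: str, model: ErrorModel = DEFAULT_MODEL
) -> np.ndarray:
    """Relative likelihood of each candidate copy number given a PRT estimate.

    The measurement m is modelled as Gaussian with mean N and standard
    deviation ``sigma_rel[assay] * N`` for each candidate N.  The returned row
    spans ``model.copy_numbers`` and is rescaled to a maximum of exactly 1.
    A missing measurement (``None``) yields an all-ones (uninformative) row.
    """
    ns = model.copy_numbers.astype(float)
    if m is None:
        return np.ones_like(ns)
    if not math.isfinite(m) or m <= 0:
        raise InvalidMeasurementError(f"PRT measurement must be > 0, got {m!r}")
    try:
        sigma = model.sigma_rel[assay]
    except KeyError:
        raise ConfigurationError(f"no sigma_rel configured for assay {assay!r}") from None
    sd = sigma * ns
    # Gaussian density including the 1/sd prefactor: the width grows with N,
    # so the prefactor genuinely discriminates between candidates.
    dens = np.exp(-0.5 * ((m - ns) / sd) ** 2) / sd
    return _finalise_row(dens, model.underflow_floor)


def ratio_relative_likelihoods(
    r: Optional[float], assay: str, model: ErrorModel = DEFAULT_MODEL
) -> np.ndarray:
    """Relative likelihood of each candidate copy number given an allelic ratio.

    For each candidate N every composition (a, b), a + b = N, a, b >= 1 is
    scored by a Gaussian kernel of the comparison metric between r and the
    expected ratio k*a/b; the row value at N is the best (or, in sum mode,
    the total) composition score.  The row is rescaled to a maximum of 1.
    A ratio of 2:1 is therefore consistent with copy number 3 but equally with
    any multiple of 3.  A missing measurement yields an all-ones row.
    """
    ns = model.copy_numbers
    if r is None:
        return np.ones(len(ns))
    if not math.isfinite(r) or r <= 0:
        raise InvalidMeasurementError(f"ratio measurement must be > 0, got {r!r}")
    try:
        sigma = model.sigma_ratio[assay]
    except KeyError:
        raise ConfigurationError(f"no sigma_ratio configured for assay {assay!r}") from None
    k = model.k.get(assay, 1.0)

    dens = np.zeros(len(ns), dtype=float)
    for i, n in enumerate(ns):
        if n < 2:
            continue  # no two-class composition exists
        scores = [
            math.exp(-0.5 * (ratio_comparison(r, expected_ratio(a, b, k), model.ratio_metric) / sigma) ** 2)
            for a, b in compositions(int(n))
        ]
        dens[i] = max(scores) if model.composition_mode == "max" else sum(scores)
    return _finalise_row(dens, model.underflow_floor)


def normalise_measurement(m: float, n_true: int) -> float:
    """Measurement divided by the assigned integer copy number.

    A PRT measurement of 6.3 for a sample with true copy number 6 has a
    normalised value of 1.05.  Pooling normalised values across copy-number
    classes is what defines the per-assay relative SD.
    """
    if n_true == 0:
        raise InvalidMeasurementError("normalised measurement undefined for n_true = 0")
    if n_true < 0:
        raise InvalidMeasurementError(f"n_true must be >= 1, got {n_true}")
    if not math.isfinite(m) or m <= 0:
        raise InvalidMeasurementError(f"measurement must be > 0, got {m!r}")
    return m / n_true


def normalised_z(m: float, n_true: int, sigma_rel: float) -> float:
    """z-score of a measurement under the relative-error model."""
    return (normalise_measurement(m, n_true) - 1.0) / sigma_rel


# ---------------------------------------------------------------------------
# Call results
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RatioCall:
    """Best integer interpretation a:b of an observed ratio at a fixed total.

    ``a`` counts the allele class in the ratio numerator (e.g. DEFA1 copies
    for the DefHae3 assay); ``b`` the complementary class; a + b equals the
    total copy number under which the call was made.
    """

    assay: str
    a: int
    b: int

    def __post_init__(self) -> None:
        if self.a < 1 or self.b < 1:
            raise InvalidMeasurementError(
                f"ratio interpretation requires both classes present, got {self.a}:{self.b}"
            )

    @property
    def total(self) -> int:
        return self.a + self.b

    def __str__(self) -> str:  # e.g. "4:3"
        return f"{self.a}:{self.b}"


@dataclass
class LikelihoodProfile:
    """Per-assay and combined relative likelihoods for one sample.

    ``rows`` maps each assay to its relative-likelihood row over
    ``copy_numbers`` (all-ones for a missing assay); ``combined`` is their
    product rescaled to a maximum of 1.  ``mlcn`` is the maximum-likelihood
    copy number and ``mr`` the minimum ratio — the factor by which support for
    the MLCN exceeds the next-best copy number.  ``anomalies`` lists assays
    whose relative likelihood at the MLCN falls below the anomaly threshold.
    """

    sample_id: str
    copy_numbers: np.ndarray
    rows: Dict[str, np.ndarray]
    combined: np.ndarray
    mlcn: int
    mr: float
    anomalies: List[str] = field(default_factory=list)
    included: bool = True
    tie: bool = False
    ratio_calls: Dict[str, RatioCall] = field(default_factory=dict)

    def row(self, assay: str) -> np.ndarray:
        return self.rows[assay]

    def combined_at(self, n: int) -> float:
        idx = np.nonzero(self.copy_numbers == n)[0]
        if len(idx) == 0:
            raise KeyError(f"copy number {n} outside profile range")
        return float(self.combined[idx[0]])
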