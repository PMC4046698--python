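"""Bundled reference values for the DEFA1A3 locus.

These are published summary data for the European DEFA1A3 typing study that
this package's likelihood framework implements: the reference-sample panel
with pulsed-field-gel-anchored integer copy numbers, worked-example
relative-likelihood tables for three samples, and the 589-sample European
diploid copy-number distribution together with its Hardy-Weinberg prediction
and three earlier cross-study distributions.  They serve as validation
inputs and as ready-made fixtures for examples; nothing here is computed by
this package.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

from .popgen import PopulationDistribution

#: Secondary reference panel: sample id -> known diploid DEFA1A3 copy number.
REFERENCE_COPY_NUMBERS: Dict[str, int] = {
    "C0007": 7,
    "C0075": 6,
    "C0150": 8,
    "C0877": 9,
    "NA07062": 5,
    "NA11998": 6,
    "NA07008": 7,
}

#: Copy-number grid of the worked-example likelihood tables (displayed range).
WORKED_EXAMPLE_COPY_NUMBERS: Tuple[int, ...] = tuple(range(2, 11))

#: Raw measurements of the worked-example samples (0 encodes missing).
WORKED_EXAMPLE_MEASUREMENTS: Dict[str, Dict[str, float]] = {
    "NA12751": {"MLT1A0": 7.07, "DEFA4": 7.03, "indel5": 1.32, "DefHae3": 2.38, "7bpdup": 2.43},
    "NA12749": {"MLT1A0": 5.71, "DEFA4": 5.21, "indel5": 0.0, "DefHae3": 3.70, "7bpdup": 3.74},
    "C0157": {"MLT1A0": 9.09, "DEFA4": 9.02, "indel5": 1.18, "DefHae3": 6.12, "7bpdup": 0.78},
}

#: Published per-assay relative-likelihood rows (3 significant figures) over
#: copy numbers 2..10 for three worked-example samples.  The NA12749 indel5
#: measurement was missing, hence its all-ones (uninformative) row.
WORKED_EXAMPLE_ROWS: Dict[str, Dict[str, List[float]]] = {
    "NA12751": {
        "MLT1A0": [1.28e-139, 2.84e-40, 1.50e-11, 6.82e-04, 0.276, 1.0, 0.471, 0.091, 0.012],
        "DEFA4": [2.15e-137, 1.97e-39, 2.37e-07, 0.010, 0.458, 1.0, 0.544, 0.156, 0.034],
        "indel5": [0.044, 2.02e-03, 0.044, 0.318, 0.044, 0.880, 0.068, 1.0, 0.318],
        "DefHae3": [5.67e-30, 0.099, 0.626, 0.038, 0.099, 0.983, 0.626, 0.172, 0.734],
        "7bpdup": [6.06e-06, 0.343, 0.155, 6.25e-03, 0.343, 1.0, 0.155, 0.343, 0.970],
    },
    "NA12749": {
        "MLT1A0": [6.56e-75, 4.43e-18, 5.99e-04, 0.538, 1.0, 0.201, 0.019, 1.44e-03, 1.16e-04],
        "DEFA4": [3.29e-56, 3.55e-12, 0.102, 1.0, 0.527, 0.095, 0.012, 1.50e-03, 2.00e-04],
        "indel5": [1.0] * 9,
        "DefHae3": [2.95e-106, 1.49e-12, 0.045, 1.0, 0.366, 0.057, 0.045, 0.550, 1.0],
        "7bpdup": [9.24e-114, 4.16e-12, 0.124, 0.873, 0.111, 7.28e-03, 0.124, 0.863, 0.873],
    },
    "C0157": {
        "MLT1A0": [1.22e-272, 1.34e-89, 9.08e-31, 2.19e-13, 9.13e-06, 0.022, 0.478, 1.0, 0.612],
        "DEFA4": [3.54e-267, 1.78e-87, 3.73e-19, 8.65e-09, 5.47e-04, 0.086, 0.650, 1.0, 0.649],
        "indel5": [0.503, 1.62e-04, 0.503, 0.058, 0.503, 0.329, 0.503, 0.637, 0.503],
        "DefHae3": [0.0, 1.88e-63, 6.26e-18, 7.72e-06, 0.053, 0.734, 0.958, 0.486, 0.171],
        "7bpdup": [0.194, 1.54e-05, 0.194, 0.351, 0.194, 0.938, 0.194, 0.985, 0.351],
    },
}

#: Published combined rows over copy numbers 2..10, and the (MLCN, MR) calls.
WORKED_EXAMPLE_COMBINED: Dict[str, List[float]] = {
    "NA12751": [4.87e-312, 4.41e-83, 1.76e-20, 6.14e-10, 2.20e-04, 1.0, 1.96e-03, 9.67e-04, 1.10e-04],
    "NA12749": [0.0, 2.08e-52, 7.25e-07, 1.0, 0.045, 1.68e-05, 2.72e-06, 2.19e-06, 4.31e-08],
    "C0157": [0.0, 3.66e-247, 6.79e-67, 9.71e-28, 8.54e-11, 1.37e-03, 0.095, 1.0, 0.039],
}

WORKED_EXAMPLE_CALLS: Dict[str, Tuple[int, float]] = {
    "NA12751": (7, 511.47),
    "NA12749": (5, 21.99),
    "C0157": (9, 10.50),
}

#: Published best integer interpretations (a:b at the MLCN) of each observed
#: ratio, for the five published worked examples.
WORKED_EXAMPLE_RATIO_INTERPRETATIONS: Dict[str, Dict[str, Tuple[float, int, Tuple[int, int]]]] = {
    # sample -> assay -> (observed ratio, MLCN, (a, b))
    "NA12751": {"indel5": (1.32, 7, (4, 3)), "DefHae3": (2.38, 7, (5, 2)), "7bpdup": (0.41, 7, (2, 5))},
    "C00528": {"indel5": (1.07, 8, (4, 4)), "DefHae3": (5.66, 8, (7, 1)), "7bpdup": (0.60, 8, (3, 5))},
    "NA12749": {"DefHae3": (3.70, 5, (4, 1)), "7bpdup": (3.74, 5, (4, 1))},
    "C0157": {"indel5": (1.18, 9, (5, 4)), "DefHae3": (6.12, 9, (8, 1)), "7bpdup": (0.78, 9, (4, 5))},
    "NA12778": {"indel5": (1.12, 6, (3, 3)), "DefHae3": (5.49, 6, (5, 1)), "7bpdup": (0.21, 6, (1, 5))},
}

#: Diploid copy-number class labels shared by all bundled distributions.
EUROPEAN_CLASSES: Tuple[str, ...] = ("<=3", "4", "5", "6", "7", "8", "9", "10", "11", "12+")

#: Observed diploid copy-number counts among the 589 European samples.
EUROPEAN_OBSERVED_COUNTS: Tuple[int, ...] = (1, 28, 69, 117, 121, 129, 64, 37, 13, 10)

#: Hardy-Weinberg class probabilities predicted from the 179 segregation-
#: resolved haplotypes (printed to 3 decimals).
EUROPEAN_HWE_PREDICTED: Tuple[float, ...] = (
    0.004, 0.045, 0.129, 0.177, 0.215, 0.205, 0.113, 0.085, 0.017, 0.010,
)

#: Earlier studies' class frequencies (same classes) and their sample sizes.
CROSS_STUDY_FREQUENCIES: Dict[str, Tuple[Tuple[float, ...], int]] = {
    "Aldred": ((0.0, 0.027, 0.144, 0.261, 0.243, 0.198, 0.108, 0.009, 0.009, 0.0), 111),
    "Linzmeier": ((0.0, 0.0, 0.037, 0.0, 0.111, 0.111, 0.111, 0.259, 0.074, 0.296), 27),
    "Nuytten": ((0.006, 0.037, 0.192, 0.372, 0.257, 0.087, 0.043, 0.006, 0.0, 0.0), 344),
}


def european_observed() -> PopulationDistribution:
    """Observed diploid copy-number distribution of the 589-sample cohort."""
    return PopulationDistribution(classes=EUROPEAN_CLASSES, counts=EUROPEAN_OBSERVED_COUNTS)


def european_hwe_predicted() -> PopulationDistribution:
    """Published HWE-predicted class probabilities (renormalised from print)."""
    total = sum(EUROPEAN_HWE_PREDICTED)
    return PopulationDistribution(
        classes=EUROPEAN_CLASSES,
        probabilities=tuple(p / total for p in EUROPEAN_HWE_PREDICTED),
    )


def cross_study_counts(study: str) -> PopulationDistribution:
    """Reconstructed class counts for an earlier study (freq x n, rounded)."""
    freqs, n = CROSS_STUDY_FREQUENCIES[study]
    counts = tuple(int(round(f * n)) for f in freqs)
    return PopulationDistribution(classes=EUROPEAN_CLASSES, counts=counts)
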