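"""Synthetic cohorts, measurement panels and pedigrees.

The generator mirrors the statistical structure the caller assumes: diploid
samples are two haplotypes drawn independently from a haplotype frequency
table (Hardy-Weinberg equilibrium); each haplotype carries a total gene copy
number and a variant composition (DEFA3 / indel5-deleted / 7bp-duplicated
counts); observed PRT values are Gaussian around the true diploid total with
SD ``sigma_rel * N``; observed allelic ratios are drawn around the integer
composition ratio k*a/b under the configured comparison metric (log-normal
noise for the default log metric).  A ratio assay whose sample carries only
one variant class produces a single electrophoresis peak and is therefore
emitted as missing, as is any assay masked by the per-assay missing rate.

The default haplotype table was chosen once, by least-squares matching of its
Hardy-Weinberg diploid distribution to the observed European copy-number
distribution bundled in :mod:`defacall.reference_data`, with variant
compositions patterned on the worked examples (one or no DEFA3 gene per
haplotype, roughly half of repeats indel5-deleted, most repeats
7bp-duplicated).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .models import ALL_ASSAYS, DEFAULT_MODEL, ErrorModel, MeasurementPanel, RATIO_ASSAYS
from .pedigree import Member, PedigreeFamily, Totals
from .popgen import Haplotype, HaplotypeSet

__all__ = [
    "TruthRecord",
    "default_haplotype_set",
    "simulate_cohort",
    "simulate_panel",
    "simulate_families",
]

RngLike = Union[int, np.random.Generator, None]


def _rng(seed: RngLike) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one simulated diploid sample."""

    sample_id: str
    hap1: Haplotype
    hap2: Haplotype

    @property
    def total_copies(self) -> int:
        return self.hap1.copies + self.hap2.copies

    def variant_total(self, name: str) -> int:
        v1 = getattr(self.hap1, name)
        v2 = getattr(self.hap2, name)
        return (v1 or 0) + (v2 or 0)

    def totals(self) -> Totals:
        return Totals(
            copies=self.total_copies,
            defa3=self.variant_total("defa3"),
            del5=self.variant_total("del5"),
            dup7=self.variant_total("dup7"),
        )


# Haplotype copy-number frequencies fitted once (least squares) so that the
# HWE self-convolution approximates the observed European diploid
# distribution; compositions are fixed per entry.
_DEFAULT_ENTRIES: Tuple[Tuple[Tuple[int, int, int, int], float], ...] = (
    # (copies, defa3, del5, dup7), frequency
    ((1, 0, 0, 1), 0.016),
    ((1, 1, 1, 0), 0.015),
    ((2, 0, 1, 2), 0.100),
    ((2, 1, 1, 1), 0.091),
    ((3, 0, 1, 2), 0.110),
    ((3, 1, 2, 2), 0.108),
    ((4, 0, 2, 3), 0.200),
    ((4, 1, 2, 3), 0.186),
    ((5, 1, 2, 4), 0.050),
    ((5, 0, 3, 3), 0.045),
    ((6, 1, 3, 4), 0.040),
    ((6, 2, 3, 5), 0.024),
    ((7, 1, 3, 5), 0.015),
)


def default_haplotype_set() -> HaplotypeSet:
    """Default European-like haplotype frequency table (see module docstring)."""
    return HaplotypeSet(
        entries=tuple((Haplotype(*h), f) for h, f in _DEFAULT_ENTRIES)
    )


def simulate_cohort(
    haps: HaplotypeSet, n: int, seed: RngLike = None, id_prefix: str = "SIM"
) -> List[TruthRecord]:
    """Draw n diploid samples under Hardy-Weinberg equilibrium.

    The two haplotypes of each sample are independent draws from the
    frequency table, so a pair (h1, h2) occurs with probability f(h1)*f(h2).
    Reproducible for a given seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _rng(seed)
    hap_list = [h for h, _ in haps.entries]
    probs = np.array([f for _, f in haps.entries])
    probs = probs / probs.sum()
    idx = rng.choice(len(hap_list), size=(n, 2), p=probs)
    width = len(str(n))
    return [
        TruthRecord(
            sample_id=f"{id_prefix}{i + 1:0{width}d}",
            hap1=hap_list[a],
            hap2=hap_list[b],
        )
        for i, (a, b) in enumerate(idx)
    ]


def _true_ratio(truth: TruthRecord, assay: str) -> Optional[float]:
    """Expected (uncalibrated) two-peak ratio for a sample, or None if one
    variant class is absent (single peak -> no ratio)."""
    n = truth.total_copies
    if assay == "indel5":
        a, b = truth.variant_total("del5"), n - truth.variant_total("del5")
    elif assay == "DefHae3":
        a, b = n - truth.variant_total("defa3"), truth.variant_total("defa3")
    elif assay == "7bpdup":
        a, b = n - truth.variant_total("dup7"), truth.variant_total("dup7")
    else:
        raise ValueError(f"not a ratio assay: {assay}")
    if a == 0 or b == 0:
        return None
    return a / b


def simulate_panel(
    truth: Sequence[TruthRecord],
    model: ErrorModel = DEFAULT_MODEL,
    seed: RngLike = None,
    missing_rate: Union[float, Dict[str, float]] = 0.0,
) -> List[MeasurementPanel]:
    """Noisy measurement panels for a list of true samples.

    PRT values: Gaussian around the true diploid total N with SD
    ``sigma_rel * N`` (the relative-error model the caller assumes).  Ratio
    values: the composition ratio k*a/b perturbed under the model's
    comparison metric — multiplicative log-normal noise for the log metric,
    additive Gaussian for the linear metric.  ``missing_rate`` masks each
    assay independently (a scalar applies to all assays); structural
    missingness (one-peak ratios) is applied regardless.
    """
    rng = _rng(seed)
    if not isinstance(missing_rate, dict):
        missing_rate = {a: float(missing_rate) for a in ALL_ASSAYS}
    panels = []
    for t in truth:
        n = t.total_copies
        values: Dict[str, float] = {}
        for assay, sigma in model.sigma_rel.items():
            m = n * (1.0 + sigma * rng.standard_normal())
            values[assay] = max(m, 1e-9)  # a true PRT value of 0 is never measured
        for assay in RATIO_ASSAYS:
            true = _true_ratio(t, assay)
            if true is None:
                values[assay] = 0.0
                continue
            expected = model.k.get(assay, 1.0) * true
            sig = model.sigma_ratio[assay]
            if model.ratio_metric == "log":
                r = expected * float(np.exp(sig * rng.standard_normal()))
            else:
                r = max(expected + sig * rng.standard_normal(), 1e-9)
            values[assay] = r
        for assay in ALL_ASSAYS:
            if missing_rate.get(assay, 0.0) > 0 and rng.random() < missing_rate[assay]:
                values[assay] = 0.0
        panels.append(MeasurementPanel.from_values(t.sample_id, values))
    return panels


def simulate_families(
    haps: HaplotypeSet,
    n_families: int,
    n_children: int = 4,
    seed: RngLike = None,
    three_generation: bool = True,
) -> List[Tuple[PedigreeFamily, Dict[str, Tuple[Haplotype, Haplotype]]]]:
    """Simulate families with fully observed diploid totals.

    Each family draws founder haplotypes from the frequency table under HWE;
    children inherit one haplotype from each parent uniformly at random.  In
    three-generation mode the founders are four grandparents whose children
    (the two parents) then produce ``n_children`` offspring, the structure
    used for segregation-based haplotype counting.  Returns each family
    alongside the true per-member haplotype pairs.
    """
    rng = _rng(seed)
    hap_list = [h for h, _ in haps.entries]
    probs = np.array([f for _, f in haps.entries])
    probs = probs / probs.sum()

    def draw_pair() -> Tuple[Haplotype, Haplotype]:
        a, b = rng.choice(len(hap_list), size=2, p=probs)
        return hap_list[a], hap_list[b]

    def totals_of(pair: Tuple[Haplotype, Haplotype]) -> Totals:
        h1, h2 = pair
        return Totals(
            copies=h1.copies + h2.copies,
            defa3=(h1.defa3 or 0) + (h2.defa3 or 0),
            del5=(h1.del5 or 0) + (h2.del5 or 0),
            dup7=(h1.dup7 or 0) + (h2.dup7 or 0),
        )

    out = []
    for fam_i in range(n_families):
        fid = f"FAM{fam_i + 1:03d}"
        truth: Dict[str, Tuple[Haplotype, Haplotype]] = {}
        members: List[Member] = []

        def add(mid: str, pair, father=None, mother=None, sex=None):
            truth[mid] = pair
            members.append(
                Member(id=mid, father=father, mother=mother, sex=sex, totals=totals_of(pair))
            )

        if three_generation:
            for gp, sex in (("pgf", "M"), ("pgm", "F"), ("mgf", "M"), ("mgm", "F")):
                add(f"{fid}-{gp}", draw_pair(), sex=sex)
            father_pair = (truth[f"{fid}-pgf"][rng.integers(2)], truth[f"{fid}-pgm"][rng.integers(2)])
            add(f"{fid}-f", father_pair, father=f"{fid}-pgf", mother=f"{fid}-pgm", sex="M")
            mother_pair = (truth[f"{fid}-mgf"][rng.integers(2)], truth[f"{fid}-mgm"][rng.integers(2)])
            add(f"{fid}-m", mother_pair, father=f"{fid}-mgf", mother=f"{fid}-mgm", sex="F")
        else:
            add(f"{fid}-f", draw_pair(), sex="M")
            add(f"{fid}-m", draw_pair(), sex="F")
        for c in range(n_children):
            pair = (truth[f"{fid}-f"][rng.integers(2)], truth[f"{fid}-m"][rng.integers(2)])
            add(f"{fid}-c{c + 1}", pair, father=f"{fid}-f", mother=f"{fid}-m")
        out.append((PedigreeFamily(family_id=fid, members=tuple(members)), truth))
    return out
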