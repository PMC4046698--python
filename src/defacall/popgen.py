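"""Population-level summaries for a multi-allelic CNV.

Three tasks live here:

* convolving haplotype copy-number frequencies into the diploid copy-number
  distribution expected under Hardy-Weinberg equilibrium (a diploid is an
  independent draw of two haplotypes, so P(n) = sum over h1+h2=n of
  f(h1)*f(h2));
* chi-square comparison of copy-number distributions, either against expected
  class probabilities (goodness of fit, e.g. observed vs HWE prediction) or
  between two observed cohorts (contingency test, e.g. cross-study
  comparisons), with an optional Monte-Carlo null for small expected counts;
* quantifying how well a tag SNP predicts copy number: r-squared of copy
  number on allele dose, and a genotype x copy-number-class contingency test.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import stats

from .models import DefacallError, InsufficientDataError

__all__ = [
    "Haplotype",
    "HaplotypeSet",
    "PopulationDistribution",
    "ComparisonResult",
    "AssociationResult",
    "hwe_expected",
    "compare_distributions",
    "snp_cnv_association",
]

VARIANTS = ("defa3", "del5", "dup7")


@dataclass(frozen=True)
class Haplotype:
    """One DEFA1A3 haplotype: total gene copies and variant composition.

    ``copies`` counts gene copies on the haplotype (partial repeat included).
    The three variant counts — DEFA3 genes, indel5-deleted repeats and
    7bp-duplicated repeats — may each be ``None`` when unresolved; when
    present they cannot exceed ``copies``.
    """

    copies: int
    defa3: Optional[int] = None
    del5: Optional[int] = None
    dup7: Optional[int] = None

    def __post_init__(self) -> None:
        if self.copies < 0:
            raise DefacallError(f"haplotype copy number must be >= 0, got {self.copies}")
        for name in VARIANTS:
            v = getattr(self, name)
            if v is not None and not 0 <= v <= self.copies:
                raise DefacallError(
                    f"variant count {name}={v} outside 0..{self.copies}"
                )

    def key(self) -> Tuple:
        return (self.copies, self.defa3, self.del5, self.dup7)


@dataclass(frozen=True)
class HaplotypeSet:
    """Haplotype frequency table: (haplotype, frequency) entries summing to 1."""

    entries: Tuple[Tuple[Haplotype, float], ...]

    def __post_init__(self) -> None:
        if not self.entries:
            raise DefacallError("empty haplotype set")
        total = sum(f for _, f in self.entries)
        if abs(total - 1.0) > 1e-9:
            raise DefacallError(f"haplotype frequencies sum to {total}, not 1")
        if any(f < 0 for _, f in self.entries):
            raise DefacallError("negative haplotype frequency")

    @classmethod
    def from_mapping(cls, freqs: Mapping[Union[int, Haplotype], float]) -> "HaplotypeSet":
        """Build from {copy number: frequency} or {Haplotype: frequency}."""
        entries = []
        for h, f in freqs.items():
            if not isinstance(h, Haplotype):
                h = Haplotype(copies=int(h))
            entries.append((h, float(f)))
        return cls(entries=tuple(entries))

    def copy_number_frequencies(self) -> Dict[int, float]:
        """Marginal frequency of each haplotype copy number."""
        out: Dict[int, float] = {}
        for h, f in self.entries:
            out[h.copies] = out.get(h.copies, 0.0) + f
        return dict(sorted(out.items()))

    @property
    def mean_copies(self) -> float:
        return sum(h.copies * f for h, f in self.entries)


# ---------------------------------------------------------------------------
# Diploid copy-number distributions
# ---------------------------------------------------------------------------

_LE_RE = re.compile(r"^(?:<=|≤)\s*(\d+)$")
_GE_RE = re.compile(r"^(\d+)\+$")


def parse_class_label(label: str) -> Tuple[int, int]:
    """Inclusive (lo, hi) integer range of a class label.

    Supports plain integers plus the open-ended bins "<=3" (or "≤3") and
    "12+"; open ends are represented by 0 and a large sentinel respectively.
    """
    label = str(label).strip()
    m = _LE_RE.match(label)
    if m:
        return (0, int(m.group(1)))
    m = _GE_RE.match(label)
    if m:
        return (int(m.group(1)), 10**6)
    return (int(label), int(label))


@dataclass(frozen=True)
class PopulationDistribution:
    """Diploid copy-number class distribution, as counts and/or probabilities.

    ``classes`` are ordered labels, allowing open-ended end bins.  A
    distribution may carry observed integer ``counts`` (with ``n`` their
    total), expected ``probabilities``, or both.
    """

    classes: Tuple[str, ...]
    counts: Optional[Tuple[float, ...]] = None
    probabilities: Optional[Tuple[float, ...]] = None

    def __post_init__(self) -> None:
        if self.counts is None and self.probabilities is None:
            raise DefacallError("distribution needs counts or probabilities")
        for v, name in ((self.counts, "counts"), (self.probabilities, "probabilities")):
            if v is not None and len(v) != len(self.classes):
                raise DefacallError(f"{name} length does not match classes")
        if self.probabilities is not None:
            total = sum(self.probabilities)
            if abs(total - 1.0) > 1e-6:
                raise DefacallError(f"probabilities sum to {total}, not 1")

    @classmethod
    def from_counts(cls, counts: Mapping[str, float]) -> "PopulationDistribution":
        return cls(classes=tuple(counts), counts=tuple(float(v) for v in counts.values()))

    @classmethod
    def from_probabilities(cls, probs: Mapping[str, float]) -> "PopulationDistribution":
        return cls(
            classes=tuple(probs), probabilities=tuple(float(v) for v in probs.values())
        )

    @property
    def n(self) -> Optional[int]:
        return None if self.counts is None else int(round(sum(self.counts)))

    def probs(self) -> np.ndarray:
        """Class probabilities (from counts if not given explicitly)."""
        if self.probabilities is not None:
            return np.asarray(self.probabilities, dtype=float)
        c = np.asarray(self.counts, dtype=float)
        return c / c.sum()

    def _representative_values(self) -> np.ndarray:
        # Open-ended bins are represented by their closed edge; adequate for
        # medians and means over interior-dominated distributions.
        vals = []
        for label in self.classes:
            lo, hi = parse_class_label(label)
            vals.append(hi if lo == 0 else lo if hi >= 10**6 else lo)
        return np.asarray(vals, dtype=float)

    def median(self) -> float:
        """Median class value, from counts (or probabilities)."""
        vals = self._representative_values()
        w = (
            np.asarray(self.counts, dtype=float)
            if self.counts is not None
            else self.probs()
        )
        cum = np.cumsum(w)
        half = cum[-1] / 2.0
        i = int(np.searchsorted(cum, half))
        if math.isclose(cum[i], half):  # even split straddles two classes
            return float((vals[i] + vals[i + 1]) / 2.0)
        return float(vals[i])

    def mean(self) -> float:
        vals = self._representative_values()
        p = self.probs()
        return float(np.dot(vals, p))


def hwe_expected(
    haps: HaplotypeSet, classes: Optional[Sequence[str]] = None
) -> PopulationDistribution:
    """Diploid copy-number distribution expected under Hardy-Weinberg.

    The diploid total is the sum of two independently drawn haplotypes, so
    its distribution is the self-convolution of the haplotype copy-number
    frequencies.  If ``classes`` is given (possibly with open-ended end
    bins), probabilities are binned accordingly; otherwise one class per
    attainable total is returned.
    """
    freqs = haps.copy_number_frequencies()
    max_h = max(freqs)
    f = np.zeros(max_h + 1)
    for h, p in freqs.items():
        f[h] = p
    g = np.convolve(f, f)  # g[n] = P(diploid total = n)

    if classes is None:
        support = np.nonzero(g > 0)[0]
        return PopulationDistribution(
            classes=tuple(str(int(n)) for n in support),
            probabilities=tuple(float(g[n]) for n in support),
        )
    probs = []
    for label in classes:
        lo, hi = parse_class_label(label)
        probs.append(float(g[lo : min(hi, len(g) - 1) + 1].sum()))
    total = sum(probs)
    if abs(total - 1.0) > 1e-9:
        raise DefacallError(
            f"classes {classes!r} cover probability {total}, not 1; widen the end bins"
        )
    return PopulationDistribution(classes=tuple(classes), probabilities=tuple(probs))


# ---------------------------------------------------------------------------
# Distribution comparison
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ComparisonResult:
    statistic: float
    p_value: float
    df: int
    method: str
    merged_classes: Tuple[str, ...] = ()


def _merge_zero_expected(
    obs: np.ndarray, exp: np.ndarray, labels: Sequence[str]
) -> Tuple[np.ndarray, np.ndarray, List[str], List[str]]:
    """Merge classes with zero expected probability into their neighbour.

    A zero-expected class with a non-zero observed count makes the chi-square
    statistic infinite; the stated policy is to pool such classes with the
    nearest non-zero-expected neighbour and report which were merged.
    """
    obs = obs.astype(float).copy()
    exp = exp.astype(float).copy()
    labels = list(labels)
    merged: List[str] = []
    while True:
        zeros = [i for i in range(len(exp)) if exp[i] == 0]
        if not zeros:
            break
        i = zeros[0]
        j = i + 1 if i + 1 < len(exp) else i - 1
        merged.append(labels[i])
        obs[j] += obs[i]
        exp[j] += exp[i]
        obs = np.delete(obs, i)
        exp = np.delete(exp, i)
        del labels[i]
    return obs, exp, labels, merged


def compare_distributions(
    observed: PopulationDistribution,
    expected: PopulationDistribution,
    monte_carlo: int = 0,
    seed: Optional[int] = None,
) -> ComparisonResult:
    """Pearson chi-square comparison of two copy-number distributions.

    If ``expected`` carries only probabilities, a goodness-of-fit test of the
    observed counts against n*p expected counts is performed (df = classes -
    1).  If ``expected`` carries counts of its own, the two cohorts are
    compared with a two-sample contingency chi-square, the appropriate test
    when both distributions are estimates.  Classes with zero expected
    probability are merged into a neighbour (reported in the result).

    ``monte_carlo`` > 0 replaces the asymptotic goodness-of-fit p-value with
    the fraction of multinomial resamples (under the expected probabilities)
    whose statistic is at least as large — preferable when expected counts
    are small.
    """
    if observed.classes != expected.classes:
        raise DefacallError("distributions have different class labels")
    if observed.counts is None:
        raise DefacallError("observed distribution must carry counts")
    obs = np.asarray(observed.counts, dtype=float)

    if expected.counts is not None:
        table = np.vstack([obs, np.asarray(expected.counts, dtype=float)])
        keep = table.sum(axis=0) > 0
        stat, p, df, _ = stats.chi2_contingency(table[:, keep])
        return ComparisonResult(
            statistic=float(stat), p_value=float(p), df=int(df), method="contingency"
        )

    n = obs.sum()
    probs = expected.probs()
    obs_m, prob_m, labels, merged = _merge_zero_expected(obs, probs, observed.classes)
    prob_m = prob_m / prob_m.sum()
    exp_counts = n * prob_m
    stat = float(np.sum((obs_m - exp_counts) ** 2 / exp_counts))
    df = len(obs_m) - 1
    if monte_carlo > 0:
        rng = np.random.default_rng(seed)
        sims = rng.multinomial(int(round(n)), prob_m, size=monte_carlo)
        sim_stats = np.sum((sims - exp_counts) ** 2 / exp_counts, axis=1)
        # +1 correction keeps the Monte-Carlo p-value strictly positive.
        p = float((np.sum(sim_stats >= stat) + 1) / (monte_carlo + 1))
        method = f"goodness-of-fit (Monte-Carlo, {monte_carlo} resamples)"
    else:
        p = float(stats.chi2.sf(stat, df))
        method = "goodness-of-fit"
    return ComparisonResult(
        statistic=stat, p_value=p, df=df, method=method, merged_classes=tuple(merged)
    )


# ---------------------------------------------------------------------------
# SNP tagging of copy number
# ---------------------------------------------------------------------------

GENOTYPE_DOSE = {"CC": 0, "CT": 1, "TC": 1, "TT": 2}


@dataclass(frozen=True)
class AssociationResult:
    """Tag-SNP vs copy-number association summary.

    ``r_squared`` is from the least-squares regression of integer copy number
    on allele dose (0/1/2); ``p_value`` from a genotype x copy-number-class
    contingency chi-square (recorded in ``method``); ``histograms`` maps each
    genotype to its copy-number histogram for plotting.
    """

    r_squared: float
    p_value: float
    statistic: float
    df: int
    method: str
    histograms: Mapping[str, Mapping[int, int]]


def snp_cnv_association(
    genotypes: Sequence[str],
    copies: Sequence[int],
    dose: Mapping[str, int] = GENOTYPE_DOSE,
) -> AssociationResult:
    """Association between a 3-state SNP genotype and integer copy number.

    Requires at least two genotype classes.  The dose regression treats the
    genotype additively; rs4300027 approximately partitions European samples
    into low (CC), medium (CT) and high (TT) DEFA1A3 copy-number categories.
    """
    if len(genotypes) != len(copies):
        raise DefacallError("genotypes and copies differ in length")
    gts = [str(g).upper() for g in genotypes]
    unknown = sorted({g for g in gts if g not in dose})
    if unknown:
        raise DefacallError(f"unrecognised genotypes: {unknown}")
    classes = sorted(set(gts))
    if len(classes) < 2:
        raise InsufficientDataError(
            "association undefined with a single genotype class"
        )
    x = np.array([dose[g] for g in gts], dtype=float)
    y = np.asarray(copies, dtype=float)
    if np.allclose(y, y[0]):
        r2 = 0.0
    else:
        r2 = float(stats.linregress(x, y).rvalue ** 2)

    cn_values = sorted(set(int(c) for c in copies))
    table = np.zeros((len(classes), len(cn_values)))
    for g, c in zip(gts, copies):
        table[classes.index(g), cn_values.index(int(c))] += 1
    keep = table.sum(axis=0) > 0
    stat, p, df, _ = stats.chi2_contingency(table[:, keep])

    hists: Dict[str, Dict[int, int]] = {g: {} for g in classes}
    for g, c in zip(gts, copies):
        hists[g][int(c)] = hists[g].get(int(c), 0) + 1
    return AssociationResult(
        r_squared=r2,
        p_value=float(p),
        statistic=float(stat),
        df=int(df),
        method="genotype x copy-number contingency chi-square",
        histograms={g: dict(sorted(h.items())) for g, h in hists.items()},
    )
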