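"""Haplotype segregation in families by exhaustive enumeration.

Each person's diploid totals (total DEFA1A3 copies, DEFA3 count,
indel5-deleted count, 7bp-duplicated count) are the sum of two haplotype
contributions.  In a family, every split of each founder's totals into two
haplotypes is enumerated, and offspring act as constraints: a child must be
explainable as one haplotype from each parent, with no recombination within
the repeat cluster and no de-novo mutation — any inconsistency is surfaced
rather than absorbed.  Solutions that differ only by swapping the two
haplotypes within a parent are merged; when more than one distinct solution
survives, the family is flagged ambiguous (flanking-SNP phase rescue is out
of scope here).  Resolved founder haplotypes pooled across families yield a
haplotype frequency table from which Hardy-Weinberg expectations can be
computed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .models import DefacallError
from .popgen import Haplotype, HaplotypeSet, VARIANTS

__all__ = [
    "Totals",
    "Member",
    "PedigreeFamily",
    "SegregationResult",
    "MendelianInconsistencyError",
    "enumerate_haplotype_solutions",
    "haplotype_frequency_table",
    "collect_founder_haplotypes",
]


class MendelianInconsistencyError(DefacallError):
    """No haplotype assignment reproduces the family's observed totals."""

    def __init__(self, family_id: str, member_id: str):
        self.family_id = family_id
        self.member_id = member_id
        super().__init__(
            f"family {family_id}: no consistent haplotype assignment; "
            f"first violation at member {member_id}"
        )


@dataclass(frozen=True)
class Totals:
    """Diploid totals for one person; any field may be missing (None).

    A missing total simply drops that constraint from the segregation search.
    """

    copies: Optional[int] = None
    defa3: Optional[int] = None
    del5: Optional[int] = None
    dup7: Optional[int] = None

    def __post_init__(self) -> None:
        for name in ("copies",) + VARIANTS:
            v = getattr(self, name)
            if v is not None and v < 0:
                raise DefacallError(f"negative total {name}={v}")
            if v is not None and name != "copies" and self.copies is not None and v > self.copies:
                raise DefacallError(f"variant total {name}={v} exceeds copies={self.copies}")


@dataclass(frozen=True)
class Member:
    id: str
    father: Optional[str] = None
    mother: Optional[str] = None
    sex: Optional[str] = None
    totals: Totals = field(default_factory=Totals)

    def __post_init__(self) -> None:
        if (self.father is None) != (self.mother is None):
            raise DefacallError(f"member {self.id}: needs 0 or 2 recorded parents")

    @property
    def is_founder(self) -> bool:
        return self.father is None


@dataclass(frozen=True)
class PedigreeFamily:
    """Up-to-three-generation family with per-member diploid totals."""

    family_id: str
    members: Tuple[Member, ...]

    def __post_init__(self) -> None:
        ids = [m.id for m in self.members]
        if len(set(ids)) != len(ids):
            raise DefacallError(f"family {self.family_id}: duplicate member ids")
        by_id = {m.id: m for m in self.members}
        for m in self.members:
            for p in (m.father, m.mother):
                if p is not None and p not in by_id:
                    raise DefacallError(
                        f"family {self.family_id}: member {m.id} has unknown parent {p}"
                    )
        # Cycle check via depth-first colouring of the parent graph.
        state: Dict[str, int] = {}

        def visit(i: str) -> None:
            if state.get(i) == 1:
                raise DefacallError(f"family {self.family_id}: parent links form a cycle")
            if state.get(i) == 2:
                return
            state[i] = 1
            m = by_id[i]
            for p in (m.father, m.mother):
                if p is not None:
                    visit(p)
            state[i] = 2

        for i in ids:
            visit(i)

    def member(self, member_id: str) -> Member:
        for m in self.members:
            if m.id == member_id:
                return m
        raise KeyError(member_id)

    @property
    def founders(self) -> Tuple[Member, ...]:
        return tuple(m for m in self.members if m.is_founder)

    def topological_order(self) -> List[Member]:
        """Members ordered so that parents precede their offspring."""
        by_id = {m.id: m for m in self.members}
        seen: Dict[str, bool] = {}
        order: List[Member] = []

        def visit(i: str) -> None:
            if seen.get(i):
                return
            seen[i] = True
            m = by_id[i]
            for p in (m.father, m.mother):
                if p is not None:
                    visit(p)
            order.append(m)

        for m in self.members:
            visit(m.id)
        return order


# ---------------------------------------------------------------------------
# Enumeration
# ---------------------------------------------------------------------------

Solution = Dict[str, Tuple[Haplotype, Haplotype]]


@dataclass(frozen=True)
class SegregationResult:
    family_id: str
    solutions: Tuple[Solution, ...]
    ambiguous: bool

    @property
    def unique_solution(self) -> Optional[Solution]:
        return self.solutions[0] if len(self.solutions) == 1 else None

    def founder_haplotypes(self, family: "PedigreeFamily") -> List[Haplotype]:
        """Founder haplotypes of the unique solution (empty if ambiguous)."""
        sol = self.unique_solution
        if sol is None:
            return []
        out: List[Haplotype] = []
        for m in family.founders:
            out.extend(sol[m.id])
        return out


def _hap_sort_key(h: Haplotype) -> Tuple:
    return tuple(-1 if v is None else v for v in h.key())


def _variant_splits(total: Optional[int], c1: int, c2: int) -> List[Tuple[Optional[int], Optional[int]]]:
    if total is None:
        return [(None, None)]
    lo = max(0, total - c2)
    hi = min(total, c1)
    return [(v, total - v) for v in range(lo, hi + 1)]


def _search_order(family: PedigreeFamily) -> List[Member]:
    """Topological order that interleaves constraints with founder choices.

    Any member whose parents are already placed is scheduled before further
    founders, so that e.g. a father's totals prune the paternal grandparents'
    splits before the maternal side is even enumerated.
    """
    placed: Dict[str, bool] = {}
    remaining = list(family.members)
    order: List[Member] = []
    while remaining:
        nxt = next(
            (m for m in remaining if not m.is_founder and placed.get(m.father) and placed.get(m.mother)),
            None,
        )
        if nxt is None:
            nxt = next(m for m in remaining if m.is_founder)
        remaining.remove(nxt)
        placed[nxt.id] = True
        order.append(nxt)
    return order


def founder_splits(totals: Totals, max_hap_copies: int = 5) -> List[Tuple[Haplotype, Haplotype]]:
    """All unordered splits of one person's totals into two haplotypes.

    Haplotype copy numbers are searched in 0..max_hap_copies (most DEFA1A3
    repeat alleles carry between 1 and 5 gene copies; zero-copy haplotypes
    are permitted).  Variant counts split over the two haplotypes subject to
    count <= copies; a missing total leaves that dimension unconstrained.
    """
    if totals.copies is not None:
        copy_pairs = [
            (c1, totals.copies - c1)
            for c1 in range(max(0, totals.copies - max_hap_copies), min(totals.copies, max_hap_copies) + 1)
        ]
    else:
        copy_pairs = [
            (c1, c2)
            for c1 in range(max_hap_copies + 1)
            for c2 in range(max_hap_copies + 1)
        ]
    out = []
    seen = set()
    for c1, c2 in copy_pairs:
        for d1, d2 in _variant_splits(totals.defa3, c1, c2):
            for e1, e2 in _variant_splits(totals.del5, c1, c2):
                for u1, u2 in _variant_splits(totals.dup7, c1, c2):
                    try:
                        h1 = Haplotype(c1, d1, e1, u1)
                        h2 = Haplotype(c2, d2, e2, u2)
                    except DefacallError:
                        continue  # variant count exceeds haplotype copies
                    pair = tuple(sorted((h1, h2), key=_hap_sort_key))
                    if pair not in seen:
                        seen.add(pair)
                        out.append(pair)
    return out


def _pair_matches(totals: Totals, h1: Haplotype, h2: Haplotype) -> bool:
    """Do two transmitted haplotypes reproduce a person's observed totals?

    A constraint applies only when the observed total and both haplotype
    contributions are known; unknowns drop the constraint.
    """
    if totals.copies is not None and h1.copies + h2.copies != totals.copies:
        return False
    for name in VARIANTS:
        t = getattr(totals, name)
        v1 = getattr(h1, name)
        v2 = getattr(h2, name)
        if t is not None and v1 is not None and v2 is not None and v1 + v2 != t:
            return False
    return True


def enumerate_haplotype_solutions(
    family: PedigreeFamily, max_hap_copies: int = 5
) -> SegregationResult:
    """Exhaustively enumerate haplotype assignments consistent with a family.

    Every founder's totals are split into two haplotypes in all possible
    ways; every non-founder receives one haplotype from each parent, and the
    assignment is retained only if each member's observed totals are
    reproduced exactly.  Raises :class:`MendelianInconsistencyError` when no
    assignment survives; sets ``ambiguous`` when more than one distinct
    solution (after within-parent relabelling) remains.
    """
    order = _search_order(family)
    non_founders = [m for m in order if not m.is_founder]
    if not non_founders:
        raise DefacallError(f"family {family.family_id}: no offspring with recorded parents")

    split_options = {
        m.id: founder_splits(m.totals, max_hap_copies) for m in family.founders
    }
    for m in family.founders:
        if not split_options[m.id]:
            raise MendelianInconsistencyError(family.family_id, m.id)

    solutions: List[Solution] = []
    satisfied: Dict[str, bool] = {m.id: m.is_founder for m in order}
    assignment: Solution = {}

    def recurse(i: int) -> None:
        if i == len(order):
            solutions.append(dict(assignment))
            return
        m = order[i]
        if m.is_founder:
            for pair in split_options[m.id]:
                assignment[m.id] = pair
                recurse(i + 1)
            del assignment[m.id]
        else:
            fpair = assignment[m.father]
            mpair = assignment[m.mother]
            for hf, hm in itertools.product(fpair, mpair):
                if _pair_matches(m.totals, hf, hm):
                    satisfied[m.id] = True
                    assignment[m.id] = (hf, hm)
                    recurse(i + 1)
                    del assignment[m.id]

    recurse(0)

    if not solutions:
        violator = next((m.id for m in order if not satisfied[m.id]), order[-1].id)
        raise MendelianInconsistencyError(family.family_id, violator)

    # Merge solutions equivalent up to within-parent haplotype relabelling:
    # canonicalise every member's pair as an unordered (sorted) pair.
    canonical: Dict[Tuple, Solution] = {}
    for sol in solutions:
        key = tuple(
            (mid, tuple(sorted(pair, key=_hap_sort_key)))
            for mid, pair in sorted(sol.items())
        )
        canonical.setdefault(key, sol)
    merged = tuple(canonical.values())
    return SegregationResult(
        family_id=family.family_id, solutions=merged, ambiguous=len(merged) > 1
    )


# ---------------------------------------------------------------------------
# Haplotype frequency tables
# ---------------------------------------------------------------------------


def collect_founder_haplotypes(
    results: Iterable[Tuple[PedigreeFamily, SegregationResult]]
) -> List[Haplotype]:
    """Founder haplotypes from every family with a unique solution."""
    out: List[Haplotype] = []
    for family, result in results:
        out.extend(result.founder_haplotypes(family))
    return out


def haplotype_frequency_table(haplotypes: Sequence[Haplotype]) -> HaplotypeSet:
    """Frequency table of distinct haplotypes among resolved founders.

    Haplotypes are keyed by copy number plus whatever variant composition is
    resolved; with no composition data they collapse to copy number alone.
    """
    if not haplotypes:
        raise DefacallError("no resolved founder haplotypes")
    counts: Dict[Tuple, Tuple[Haplotype, int]] = {}
    for h in haplotypes:
        key = h.key()
        prev = counts.get(key)
        counts[key] = (h, (prev[1] if prev else 0) + 1)
    total = len(haplotypes)
    entries = tuple(
        (h, c / total) for h, c in sorted(counts.values(), key=lambda hc: _hap_sort_key(hc[0]))
    )
    return HaplotypeSet(entries=entries)
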