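"""Likelihood-ratio (LOD) parentage from co-dominant microsatellite
genotypes and construction of mother-defined families.

The LOD of a candidate parent is the natural log of the ratio between the
probability of the offspring genotype given that the candidate transmitted
one allele (the other drawn from population allele frequencies) and its
unconditional Hardy-Weinberg probability, summed over loci. A simple error
mixture makes Mendelian-incompatible loci contribute a finite ``ln e``
penalty instead of minus infinity when ``error_rate`` e > 0: with
probability e the observed single-locus genotype is an unrelated
Hardy-Weinberg draw.

Because of multiple paternity (and sperm storage) in *S. canicula*,
families are defined by the mothers; the minimum number of unsampled
fathers in a family is bounded from below by the per-locus count of
paternal alleles not carried by the mother.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

LocusGenotype = tuple[int, int]  # unordered allele-size pair


@dataclass
class MicrosatGenotype:
    individual: str
    loci: dict[str, LocusGenotype | None]  # None = missing at that locus

    def __post_init__(self) -> None:
        norm = {}
        for locus, pair in self.loci.items():
            if pair is None:
                norm[locus] = None
                continue
            a, b = pair
            if a <= 0 or b <= 0:
                raise ValueError(
                    f"{self.individual}/{locus}: allele sizes must be positive")
            norm[locus] = (min(a, b), max(a, b))
        self.loci = norm


@dataclass
class AlleleFrequencies:
    freqs: dict[str, dict[int, float]]  # locus -> allele -> frequency

    def __post_init__(self) -> None:
        for locus, fr in self.freqs.items():
            total = sum(fr.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{locus}: frequencies sum to {total}, not 1")
            if any(p <= 0 for p in fr.values()):
                raise ValueError(f"{locus}: non-positive frequency")

    def p(self, locus: str, allele: int) -> float:
        return self.freqs[locus].get(allele, 0.0)


def allele_frequencies(
    genotypes: Iterable[MicrosatGenotype],
) -> AlleleFrequencies:
    """Counting estimator over non-missing genotypes, per locus."""
    counts: dict[str, dict[int, int]] = {}
    loci_seen: set[str] = set()
    for g in genotypes:
        for locus, pair in g.loci.items():
            loci_seen.add(locus)
            if pair is None:
                continue
            d = counts.setdefault(locus, {})
            for a in pair:
                d[a] = d.get(a, 0) + 1
    missing = sorted(loci_seen - set(counts))
    if missing:
        raise ValueError(f"all genotypes missing at locus: {', '.join(missing)}")
    freqs = {
        locus: {a: n / sum(d.values()) for a, n in d.items()}
        for locus, d in counts.items()
    }
    return AlleleFrequencies(freqs)


def _hw_prob(pair: LocusGenotype, locus: str, freqs: AlleleFrequencies) -> float:
    a, b = pair
    if a == b:
        return freqs.p(locus, a) ** 2
    return 2 * freqs.p(locus, a) * freqs.p(locus, b)


def _transmit_prob(parent: LocusGenotype, allele: int) -> float:
    return (int(parent[0] == allele) + int(parent[1] == allele)) / 2


def _single_parent_prob(
    off: LocusGenotype, parent: LocusGenotype, locus: str, freqs: AlleleFrequencies
) -> float:
    a, b = off
    if a == b:
        return _transmit_prob(parent, a) * freqs.p(locus, a)
    return (_transmit_prob(parent, a) * freqs.p(locus, b)
            + _transmit_prob(parent, b) * freqs.p(locus, a))


def _pair_prob(
    off: LocusGenotype, mother: LocusGenotype, father: LocusGenotype
) -> float:
    a, b = off
    if a == b:
        return _transmit_prob(mother, a) * _transmit_prob(father, a)
    return (_transmit_prob(mother, a) * _transmit_prob(father, b)
            + _transmit_prob(mother, b) * _transmit_prob(father, a))


def lod_single_parent(
    offspring: MicrosatGenotype,
    candidate: MicrosatGenotype,
    freqs: AlleleFrequencies,
    error_rate: float = 0.0,
) -> float:
    """Natural-log likelihood ratio that the candidate is a parent of the
    offspring, versus the offspring being an unrelated population draw.
    Missing loci contribute 0. Returns -inf on Mendelian exclusion when
    ``error_rate`` is 0."""
    shared = [
        locus for locus, pair in offspring.loci.items()
        if pair is not None and candidate.loci.get(locus) is not None
    ]
    if not shared:
        raise ValueError("no shared typed loci between offspring and candidate")
    lod = 0.0
    for locus in shared:
        off, par = offspring.loci[locus], candidate.loci[locus]
        hw = _hw_prob(off, locus, freqs)
        num = (1 - error_rate) * _single_parent_prob(off, par, locus, freqs)
        num += error_rate * hw
        if num == 0.0:
            return -math.inf
        lod += math.log(num / hw)
    return lod


def lod_parent_pair(
    offspring: MicrosatGenotype,
    mother: MicrosatGenotype,
    father: MicrosatGenotype,
    freqs: AlleleFrequencies,
    error_rate: float = 0.0,
) -> float:
    """LOD of the joint hypothesis that mother and father are the parents."""
    lod = 0.0
    any_locus = False
    for locus, off in offspring.loci.items():
        m, f = mother.loci.get(locus), father.loci.get(locus)
        if off is None or m is None or f is None:
            continue
        any_locus = True
        hw = _hw_prob(off, locus, freqs)
        num = (1 - error_rate) * _pair_prob(off, m, f) + error_rate * hw
        if num == 0.0:
            return -math.inf
        lod += math.log(num / hw)
    if not any_locus:
        raise ValueError("no locus typed in all three individuals")
    return lod


def mendelian_compatible(
    offspring: MicrosatGenotype,
    mother: MicrosatGenotype,
    father: MicrosatGenotype,
) -> tuple[dict[str, bool], int]:
    """Per-locus trio compatibility (offspring formable from one allele per
    parent) and the number of mismatching loci."""
    out: dict[str, bool] = {}
    for locus, off in offspring.loci.items():
        m, f = mother.loci.get(locus), father.loci.get(locus)
        if off is None or m is None or f is None:
            continue
        a, b = off
        ok = (
            (_transmit_prob(m, a) > 0 and _transmit_prob(f, b) > 0)
            or (_transmit_prob(m, b) > 0 and _transmit_prob(f, a) > 0)
        )
        out[locus] = ok
    return out, sum(1 for ok in out.values() if not ok)


ASSIGNED = "assigned"
AMBIGUOUS = "ambiguous"
UNASSIGNED = "unassigned"


@dataclass
class ParentageResult:
    offspring: str
    mother: str | None
    mother_lod: float
    father: str | None
    father_lod: float
    pair_lod: float
    status: str


@dataclass
class Family:
    mother: str
    fathers: list[str]
    offspring: list[str]
    min_unsampled_fathers: int = 0


def _best_candidate(
    offspring: MicrosatGenotype,
    candidates: Mapping[str, MicrosatGenotype],
    freqs: AlleleFrequencies,
    error_rate: float,
    ambiguity_window: float,
) -> tuple[str | None, float, bool]:
    """Best positive-LOD candidate; ambiguous when two candidates fall
    within the LOD window of each other."""
    scored = sorted(
        (
            (lod_single_parent(offspring, cand, freqs, error_rate), cid)
            for cid, cand in candidates.items()
        ),
        reverse=True,
    )
    if not scored or scored[0][0] <= 0:
        return None, scored[0][0] if scored else -math.inf, False
    ambiguous = (
        len(scored) > 1
        and scored[1][0] > 0
        and scored[0][0] - scored[1][0] < ambiguity_window
    )
    return scored[0][1], scored[0][0], ambiguous


def min_unsampled_fathers(
    mother: MicrosatGenotype,
    offspring: Iterable[MicrosatGenotype],
) -> int:
    """Lower bound on the number of unsampled fathers from the maximum
    per-locus count of offspring alleles not carried by the mother (each
    father holds at most two)."""
    best = 0
    per_locus: dict[str, set[int]] = {}
    for off in offspring:
        for locus, pair in off.loci.items():
            m = mother.loci.get(locus)
            if pair is None or m is None:
                continue
            non_maternal = [a for a in pair if a not in m]
            per_locus.setdefault(locus, set()).update(non_maternal)
    for alleles in per_locus.values():
        best = max(best, math.ceil(len(alleles) / 2))
    return best


def assign_families(
    offspring: Mapping[str, MicrosatGenotype],
    mothers: Mapping[str, MicrosatGenotype],
    fathers: Mapping[str, MicrosatGenotype],
    freqs: AlleleFrequencies | None = None,
    error_rate: float = 0.01,
    ambiguity_window: float = 0.1,
) -> tuple[list[ParentageResult], list[Family]]:
    """Single-mother, single-father and pair analyses for every offspring.

    An offspring is ``assigned`` when the best mother and father each have a
    positive LOD, the parent-pair LOD is positive, and the pair is
    consistent with the single-parent analyses. Assigned offspring are
    grouped into mother-defined families; each family's minimum number of
    unsampled fathers is estimated from non-maternal allele counts of the
    offspring without a confidently assigned father.
    """
    overlap = (set(offspring) & set(mothers)) | (set(offspring) & set(fathers))
    if overlap:
        raise ValueError(f"candidates overlap offspring: {sorted(overlap)}")
    if freqs is None:
        freqs = allele_frequencies(
            list(offspring.values()) + list(mothers.values()) + list(fathers.values())
        )
    results: list[ParentageResult] = []
    fam_members: dict[str, list[str]] = {}
    fam_fathers: dict[str, set[str]] = {}
    unsired: dict[str, list[str]] = {}

    for oid, og in offspring.items():
        mid, mlod, m_amb = _best_candidate(
            og, mothers, freqs, error_rate, ambiguity_window)
        fid, flod, f_amb = (None, -math.inf, False)
        if fathers:
            fid, flod, f_amb = _best_candidate(
                og, fathers, freqs, error_rate, ambiguity_window)
        pair_lod = -math.inf
        if mid is not None and fid is not None:
            pair_lod = lod_parent_pair(
                og, mothers[mid], fathers[fid], freqs, error_rate)
        if mid is None:
            status = UNASSIGNED
        elif m_amb or f_amb:
            status = AMBIGUOUS
        elif fid is not None and pair_lod > 0:
            status = ASSIGNED
        elif fid is None:
            status = ASSIGNED  # mother-only assignment (unsampled father)
        else:
            status = AMBIGUOUS
        results.append(
            ParentageResult(oid, mid, mlod, fid, flod, pair_lod, status))
        if mid is not None and status != UNASSIGNED:
            fam_members.setdefault(mid, []).append(oid)
            fam_fathers.setdefault(mid, set())
            if status == ASSIGNED and fid is not None and pair_lod > 0:
                fam_fathers[mid].add(fid)
            else:
                unsired.setdefault(mid, []).append(oid)

    families = []
    for mid in sorted(fam_members):
        n_unsampled = 0
        if unsired.get(mid):
            n_unsampled = min_unsampled_fathers(
                mothers[mid], [offspring[o] for o in unsired[mid]])
        families.append(
            Family(
                mother=mid,
                fathers=sorted(fam_fathers[mid]),
                offspring=sorted(fam_members[mid]),
                min_unsampled_fathers=n_unsampled,
            )
        )
    return results, families
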