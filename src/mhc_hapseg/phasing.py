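"""Pedigree-based phasing of MHC IIbeta haplotypes from allele segregation.

The genetic architecture encoded here follows the study system: one
composite A/B locus region carrying up to two alleles per haplotype
(lineages A and B segregate in the same loci) and one separate lineage-C
locus carrying at most one allele per haplotype, which may be absent from a
chromosome altogether (hemizygosity). Genotypes are presence-only: allele
dosage is unobserved, so a parent's two haplotypes may share alleles.

Phasing is an exact search: every capacity-respecting bipartition of each
parent's allele set is enumerated, and the combination of parental
bipartitions that explains the most offspring (each offspring's allele set
must equal the union of one maternal and one paternal haplotype), with the
fewest recombinant transmissions, is reported. Ties are kept: all optimal
solutions are retained and the lexicographically first is returned, with the
multiplicity attached.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from scipy import stats

# C-slot states for a haplotype that carries no lineage-C allele.
C_ABSENT = "absent"  # the C gene is demonstrably missing from this chromosome
C_UNKNOWN = "unknown"  # absence vs homozygosity not resolved


class ArchitectureError(ValueError):
    """A genotype violates the two-locus A/B + one-locus C capacity model."""


@dataclass(frozen=True)
class Haplotype:
    """Alleles carried on one chromosome: <=2 A/B alleles, <=1 C allele."""

    ab: tuple[str, ...] = ()
    c: str | None = None
    c_state: str = field(default=C_UNKNOWN, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "ab", tuple(sorted(self.ab)))
        if len(self.ab) > 2:
            raise ArchitectureError(f"haplotype with >2 A/B alleles: {self.ab}")
        object.__setattr__(self, "ab_set", frozenset(self.ab))

    @property
    def alleles(self) -> frozenset[str]:
        return self.ab_set | ({self.c} if self.c else frozenset())

    @property
    def key(self) -> tuple:
        return (self.ab, self.c or "")

    def __repr__(self) -> str:
        c = self.c if self.c else f"<{self.c_state}>"
        return f"Hap({'+'.join(self.ab) or '-'}|{c})"


# MHC genotype C observation status
C_PRESENT = "present"
C_ABSENT_OBS = "absent"  # C amplicon worked, no C allele found
C_MISSING = "missing"  # C amplicon failed / not attempted


@dataclass
class MHCGenotype:
    """Per-individual allele presence, split by lineage slot."""

    individual: str
    ab: frozenset[str] = frozenset()
    c: frozenset[str] = frozenset()
    c_status: str = C_PRESENT

    def __post_init__(self) -> None:
        self.ab = frozenset(self.ab)
        self.c = frozenset(self.c)
        if self.c and self.c_status != C_PRESENT:
            raise ValueError(f"{self.individual}: C alleles present but status "
                             f"{self.c_status!r}")
        if not self.c and self.c_status == C_PRESENT:
            raise ValueError(f"{self.individual}: status 'present' with no C allele")

    @property
    def alleles(self) -> frozenset[str]:
        return self.ab | self.c


@dataclass
class PedigreeFamily:
    """A mother-defined family (multiple paternity expected)."""

    mother: str
    offspring: list[str]
    fathers: list[str] = field(default_factory=list)
    unknown_fathers: bool = False
    family_id: str | None = None


def enumerate_bipartitions(
    genotype: MHCGenotype, ab_capacity: int = 2, c_capacity: int = 1
) -> list[tuple[Haplotype, Haplotype]]:
    """All unordered haplotype pairs whose union is the parent's allele set.

    Alleles may sit on both haplotypes (dosage is unobserved, so homozygosity
    must be in the search space), and a single C allele generates both the
    "on haplotype 1" and "on haplotype 2" options as well as the homozygous
    one — these are the hemizygosity candidates.
    """
    ab = sorted(genotype.ab)
    cs = sorted(genotype.c)
    if len(ab) > 2 * ab_capacity:
        raise ArchitectureError(
            f"{genotype.individual}: {len(ab)} A/B alleles exceeds "
            f"2 x capacity {ab_capacity}")
    if len(cs) > 2 * c_capacity:
        raise ArchitectureError(
            f"{genotype.individual}: {len(cs)} C alleles exceeds "
            f"2 x capacity {c_capacity}")

    subsets = [
        tuple(sorted(s))
        for n in range(ab_capacity + 1)
        for s in itertools.combinations(ab, n)
    ]
    ab_pairs = set()
    full = frozenset(ab)
    for s1, s2 in itertools.combinations_with_replacement(subsets, 2):
        if frozenset(s1) | frozenset(s2) == full:
            ab_pairs.add(tuple(sorted((s1, s2))))

    no_c_state = C_ABSENT if genotype.c_status == C_ABSENT_OBS else C_UNKNOWN
    if len(cs) == 2:
        c_options = [(cs[0], cs[1]), (cs[1], cs[0])]
    elif len(cs) == 1:
        c_options = [(cs[0], None), (None, cs[0]), (cs[0], cs[0])]
    else:
        c_options = [(None, None)]

    pairs: dict[tuple, tuple[Haplotype, Haplotype]] = {}
    for (ab1, ab2) in ab_pairs:
        for c1, c2 in c_options:
            h1 = Haplotype(ab1, c1, C_UNKNOWN if c1 else no_c_state)
            h2 = Haplotype(ab2, c2, C_UNKNOWN if c2 else no_c_state)
            a, b = sorted((h1, h2), key=lambda h: h.key)
            pairs[(a.key, b.key)] = (a, b)
    return [pairs[k] for k in sorted(pairs)]


def union_explains(off: MHCGenotype, h1: Haplotype, h2: Haplotype) -> bool:
    """Does the union of two transmitted haplotypes equal the offspring's
    observed allele set? C is ignored when the offspring's C observation is
    missing."""
    if h1.ab_set | h2.ab_set != off.ab:
        return False
    if off.c_status == C_MISSING:
        return True
    contributed = {h.c for h in (h1, h2) if h.c}
    return contributed == set(off.c)


def recombinant_pair(
    h1: Haplotype, h2: Haplotype
) -> list[tuple[Haplotype, Haplotype]]:
    """Single-exchange recombinants of a parental haplotype pair at the only
    boundary observable at this marker resolution: the A/B region vs the C
    locus."""
    r1 = Haplotype(h1.ab, h2.c, h2.c_state)
    r2 = Haplotype(h2.ab, h1.c, h1.c_state)
    if (r1.key, r2.key) in ((h1.key, h2.key), (h2.key, h1.key)):
        return []
    return [(r1, r2)]


def remainder_haplotype(off: MHCGenotype, maternal: Haplotype) -> Haplotype | None:
    """Paternal haplotype implied by an offspring when the father is
    unsampled: the set-difference remainder, if it is itself a valid
    haplotype."""
    if not frozenset(maternal.ab) <= off.ab:
        return None
    rem_ab = tuple(sorted(off.ab - frozenset(maternal.ab)))
    if len(rem_ab) > 2:
        return None
    if off.c_status == C_MISSING:
        if maternal.c is not None:
            return None  # cannot verify transmission; be conservative
        return Haplotype(rem_ab, None, C_UNKNOWN)
    if off.c_status == C_ABSENT_OBS:
        if maternal.c is not None:
            return None
        return Haplotype(rem_ab, None, C_ABSENT)
    # offspring carries C
    if maternal.c is not None and maternal.c not in off.c:
        return None
    rem_c = set(off.c) - ({maternal.c} if maternal.c else set())
    if len(rem_c) > 1:
        return None
    if rem_c:
        return Haplotype(rem_ab, rem_c.pop(), C_UNKNOWN)
    # offspring C fully explained by the mother; paternal C side unknown
    return Haplotype(rem_ab, None, C_UNKNOWN)


@dataclass
class Assignment:
    """How one explained offspring's alleles decompose."""

    maternal_index: int  # 0/1 into the mother's haplotype pair
    paternal_parent: str | None  # father id, or None for an inferred external
    paternal_index: int | None  # 0/1 into that father's pair
    external: Haplotype | None = None  # inferred haplotype when father unknown
    recombinant: bool = False
    recombinant_parent: str | None = None


@dataclass
class PhasingSolution:
    family: PedigreeFamily
    parent_haplotypes: dict[str, tuple[Haplotype, Haplotype]]
    multiplicity: int = 1
    # all co-optimal solutions (including this one), canonical order;
    # downstream steps can consume the full optimum set
    alternatives: list["PhasingSolution"] = field(default_factory=list, repr=False)
    # offspring assignments are derived lazily from the parental bipartitions
    _genotypes: Mapping[str, "MHCGenotype"] | None = field(
        default=None, repr=False, compare=False)
    _allow_unknown: bool = False
    _assignments: dict[str, Assignment] | None = field(
        default=None, repr=False, compare=False)
    _unexplained: list[str] | None = field(
        default=None, repr=False, compare=False)

    def _derive(self) -> None:
        mpair = self.parent_haplotypes[self.family.mother]
        fpairs = {
            p: pair for p, pair in self.parent_haplotypes.items()
            if p != self.family.mother
        }
        assignments: dict[str, Assignment] = {}
        unexplained: list[str] = []
        for oid in self.family.offspring:
            a = _explain_offspring(
                self._genotypes[oid], mpair, fpairs, self._allow_unknown)
            if a is None:
                unexplained.append(oid)
            else:
                assignments[oid] = a
        self._assignments = assignments
        self._unexplained = unexplained

    @property
    def assignments(self) -> dict[str, Assignment]:
        if self._assignments is None:
            self._derive()
        return self._assignments

    @property
    def unexplained(self) -> list[str]:
        if self._unexplained is None:
            self._derive()
        return self._unexplained

    @property
    def n_recombinants(self) -> int:
        return sum(1 for a in self.assignments.values() if a.recombinant)

    def external_haplotype_counts(self) -> dict[tuple, tuple[Haplotype, int]]:
        counts: dict[tuple, tuple[Haplotype, int]] = {}
        for a in self.assignments.values():
            if a.external is not None:
                key = a.external.key
                hap, n = counts.get(key, (a.external, 0))
                counts[key] = (hap, n + 1)
        return counts

    def min_unsampled_fathers(self) -> int:
        """Minimum number of unsampled fathers consistent with the distinct
        inferred external haplotypes (two haplotypes per father)."""
        n_ext = len(self.external_haplotype_counts())
        return math.ceil(n_ext / 2)


def _explain_offspring(
    off: MHCGenotype,
    mother_pair: tuple[Haplotype, Haplotype],
    father_pairs: Mapping[str, tuple[Haplotype, Haplotype]],
    allow_unknown: bool,
) -> Assignment | None:
    """Find the canonical explanation of one offspring under fixed parental
    bipartitions. Non-recombinant explanations are preferred; recombinant
    ones (single A/B-vs-C exchange in exactly one parent) come next."""
    # 1. plain maternal x known-father
    for mi, mh in enumerate(mother_pair):
        for fid, fpair in father_pairs.items():
            for pi, ph in enumerate(fpair):
                if union_explains(off, mh, ph):
                    return Assignment(mi, fid, pi)
    # 2. plain maternal x external remainder
    if allow_unknown:
        for mi, mh in enumerate(mother_pair):
            rem = remainder_haplotype(off, mh)
            if rem is not None and union_explains(off, mh, rem):
                return Assignment(mi, None, None, external=rem)
    # 3. recombinant maternal
    for rm_pair in recombinant_pair(*mother_pair):
        for mi, mh in enumerate(rm_pair):
            for fid, fpair in father_pairs.items():
                for pi, ph in enumerate(fpair):
                    if union_explains(off, mh, ph):
                        return Assignment(
                            mi, fid, pi, recombinant=True,
                            recombinant_parent="mother")
            if allow_unknown:
                rem = remainder_haplotype(off, mh)
                if rem is not None and union_explains(off, mh, rem):
                    return Assignment(
                        mi, None, None, external=rem, recombinant=True,
                        recombinant_parent="mother")
    # 4. recombinant paternal
    for fid, fpair in father_pairs.items():
        for rp_pair in recombinant_pair(*fpair):
            for pi, ph in enumerate(rp_pair):
                for mi, mh in enumerate(mother_pair):
                    if union_explains(off, mh, ph):
                        return Assignment(
                            mi, fid, pi, recombinant=True,
                            recombinant_parent=fid)
    return None


def _combo_key(
    mother: str,
    mother_pair: tuple[Haplotype, Haplotype],
    father_pairs: Mapping[str, tuple[Haplotype, Haplotype]],
) -> tuple:
    parts = [(mother, mother_pair[0].key, mother_pair[1].key)]
    for fid in sorted(father_pairs):
        p = father_pairs[fid]
        parts.append((fid, p[0].key, p[1].key))
    return tuple(parts)


def phase_family(
    family: PedigreeFamily,
    genotypes: Mapping[str, MHCGenotype],
    ab_capacity: int = 2,
    c_capacity: int = 1,
) -> PhasingSolution:
    """Exact segregation-based phasing of one mother-defined family.

    Maximises the number of explained offspring, then minimises recombinant
    transmissions, over all combinations of parental bipartitions. All
    co-optimal solutions are tracked; the lexicographically first (by parent
    haplotype content) is returned with ``multiplicity`` set to the number of
    distinct optima.
    """
    if family.mother not in genotypes:
        raise KeyError(f"no genotype for mother {family.mother}")
    missing = [o for o in family.offspring if o not in genotypes]
    if missing:
        raise KeyError(f"no genotype for offspring: {', '.join(missing)}")
    mother_parts = enumerate_bipartitions(
        genotypes[family.mother], ab_capacity, c_capacity)
    father_parts = {
        f: enumerate_bipartitions(genotypes[f], ab_capacity, c_capacity)
        for f in family.fathers
        if f in genotypes
    }
    allow_unknown = family.unknown_fathers or not father_parts

    father_ids = sorted(father_parts)
    offspring = list(family.offspring)
    best_score: tuple[int, int] | None = None
    optima: dict[tuple, tuple] = {}

    off_data = [
        (oid, genotypes[oid].ab, genotypes[oid].c,
         genotypes[oid].c_status == C_MISSING)
        for oid in offspring
    ]

    def explained_set(h_pairs) -> frozenset[str]:
        """Offspring whose allele set equals the union of some pair."""
        unions = [
            (mh.ab_set | ph.ab_set,
             frozenset(x for x in (mh.c, ph.c) if x))
            for mh, ph in h_pairs
        ]
        res = set()
        for oid, ab, c, c_missing in off_data:
            for u_ab, u_c in unions:
                if u_ab == ab and (c_missing or u_c == c):
                    res.add(oid)
                    break
        return frozenset(res)

    for mpair in mother_parts:
        # external-father explanations depend only on the mother's pair
        ext_plain: set[str] = set()
        ext_rec: set[str] = set()
        if allow_unknown:
            for oid in offspring:
                off = genotypes[oid]
                if any(
                    (rem := remainder_haplotype(off, mh)) is not None
                    and union_explains(off, mh, rem)
                    for mh in mpair
                ):
                    ext_plain.add(oid)
                    continue
                for rm_pair in recombinant_pair(*mpair):
                    if any(
                        (rem := remainder_haplotype(off, mh)) is not None
                        and union_explains(off, mh, rem)
                        for mh in rm_pair
                    ):
                        ext_rec.add(oid)
                        break
        # group each father's bipartitions by their explanation signature;
        # the product runs over signatures, not bipartitions
        rec_m = recombinant_pair(*mpair)
        fgroups: dict[str, dict[tuple, list]] = {}
        for fid in father_ids:
            groups: dict[tuple, list] = {}
            for fpair in father_parts[fid]:
                sp = explained_set(
                    [(mh, ph) for mh in mpair for ph in fpair])
                rec_pairs = [
                    (mh, ph)
                    for rm in rec_m for mh in rm for ph in fpair
                ] + [
                    (mh, ph)
                    for rf in recombinant_pair(*fpair)
                    for ph in rf for mh in mpair
                ]
                sr = (explained_set(rec_pairs) - sp) if rec_pairs else frozenset()
                groups.setdefault((sp, sr), []).append(fpair)
            fgroups[fid] = groups

        for sig_choice in itertools.product(
                *(fgroups[f].keys() for f in father_ids)):
            plain = set(ext_plain)
            for sp, _ in sig_choice:
                plain |= sp
            rec = set(ext_rec)
            for _, sr in sig_choice:
                rec |= sr
            rec -= plain
            score = (len(plain) + len(rec), -len(rec))
            if best_score is not None and score < best_score:
                continue
            if best_score is None or score > best_score:
                best_score = score
                optima = {}
            # expand the signature choice back to concrete bipartitions;
            # assignments are derived lazily when a solution is consumed
            for fchoice in itertools.product(
                    *(fgroups[f][sig] for f, sig in
                      zip(father_ids, sig_choice))):
                fpairs = dict(zip(father_ids, fchoice))
                key = _combo_key(family.mother, mpair, fpairs)
                if key not in optima:
                    optima[key] = (mpair, fpairs)

    if best_score is None or best_score[0] == 0:
        alleles = sorted(
            set().union(*(genotypes[o].alleles for o in family.offspring))
            - genotypes[family.mother].alleles
        ) if family.offspring else []
        raise ValueError(
            f"no bipartition combination explains any offspring of "
            f"{family.mother}; offspring carry non-parental alleles: {alleles}"
        )

    solutions = []
    for key in sorted(optima):
        mpair, fpairs = optima[key]
        solutions.append(
            PhasingSolution(
                family=family,
                parent_haplotypes={family.mother: mpair, **fpairs},
                multiplicity=len(optima),
                _genotypes=genotypes,
                _allow_unknown=allow_unknown,
            )
        )
    primary = solutions[0]
    primary.alternatives = solutions
    return primary


def _pair_key(pair: tuple[Haplotype, Haplotype]) -> tuple:
    return tuple(sorted((pair[0].key, pair[1].key)))


def phase_families(
    families: Iterable[PedigreeFamily],
    genotypes: Mapping[str, MHCGenotype],
    ab_capacity: int = 2,
    c_capacity: int = 1,
) -> dict[str, PhasingSolution]:
    """Phase several families, reconciling parents shared between them.

    A father siring offspring of more than one mother may be phase-ambiguous
    within one family (only one of his haplotypes observed there) yet pinned
    down by another; among each family's co-optimal solutions, those whose
    shared-parent bipartitions are consistent across all families are
    preferred. Keys of the returned dict are family ids (or mother ids).
    """
    families = list(families)
    primaries = {
        (fam.family_id or fam.mother): phase_family(
            fam, genotypes, ab_capacity, c_capacity)
        for fam in families
    }
    candidates = {fid: list(sol.alternatives) for fid, sol in primaries.items()}

    parent_to_fams: dict[str, list[str]] = {}
    for fam in families:
        fid = fam.family_id or fam.mother
        for pid in [fam.mother] + list(fam.fathers):
            if pid in primaries[fid].parent_haplotypes:
                parent_to_fams.setdefault(pid, []).append(fid)

    for pid, fids in parent_to_fams.items():
        allowed = None
        for fid in fids:
            keys = {_pair_key(alt.parent_haplotypes[pid])
                    for alt in candidates[fid]}
            allowed = keys if allowed is None else allowed & keys
        if not allowed:
            continue  # no consistent phase; keep each family's own optima
        for fid in fids:
            filtered = [
                alt for alt in candidates[fid]
                if _pair_key(alt.parent_haplotypes[pid]) in allowed
            ]
            if filtered:
                candidates[fid] = filtered

    out = {}
    for fid, alts in candidates.items():
        primary = alts[0]
        primary.multiplicity = len(alts)
        primary.alternatives = alts
        out[fid] = primary
    return out


# ---------------------------------------------------------------------------
# recombination


@dataclass
class RecombinationReport:
    eligible_parents: list[str]
    n_transmissions: int
    n_recombinant: int

    @property
    def frequency(self) -> float:
        return self.n_recombinant / self.n_transmissions if self.n_transmissions else 0.0


def _parent_offspring_counts(solution: PhasingSolution) -> dict[str, int]:
    counts = {solution.family.mother: len(solution.assignments)}
    for a in solution.assignments.values():
        if a.paternal_parent is not None:
            counts[a.paternal_parent] = counts.get(a.paternal_parent, 0) + 1
    return counts


def count_recombinants(
    solutions: PhasingSolution | Iterable[PhasingSolution],
    min_offspring: int = 5,
) -> RecombinationReport:
    """Recombinant transmissions among eligible parents.

    A parent is eligible when it has at least ``min_offspring`` assigned
    offspring and its two haplotypes differ in their C slot (a parent whose
    chromosomes carry the same C composition cannot reveal an A/B-vs-C
    exchange, because the lineage-specific C amplification guarantees full
    allelic coverage either way).
    """
    if isinstance(solutions, PhasingSolution):
        solutions = [solutions]
    eligible: list[str] = []
    n_trans = 0
    n_rec = 0
    for sol in solutions:
        counts = _parent_offspring_counts(sol)
        for pid, pair in sol.parent_haplotypes.items():
            n_off = counts.get(pid, 0)
            if n_off < min_offspring:
                continue
            h1, h2 = pair
            if (h1.c or "") == (h2.c or ""):
                continue
            eligible.append(pid)
            n_trans += n_off
            for a in sol.assignments.values():
                if not a.recombinant:
                    continue
                rec_parent = (
                    sol.family.mother
                    if a.recombinant_parent == "mother"
                    else a.recombinant_parent
                )
                if rec_parent == pid:
                    n_rec += 1
    return RecombinationReport(eligible, n_trans, n_rec)


# ---------------------------------------------------------------------------
# hemizygosity


def infer_hemizygosity(
    solution: PhasingSolution, genotypes: Mapping[str, MHCGenotype]
) -> dict[tuple[str, int], str]:
    """Resolve the C slot of haplotypes that carry no C allele.

    A haplotype's C slot is ABSENT when at least one offspring assigned that
    haplotype has observed C status "absent" (the C amplification worked and
    found nothing) — the chromosome demonstrably lacks the gene. Offspring
    with C status "missing" are never evidence. Everything else stays
    UNKNOWN (true absence vs homozygosity unresolvable).
    """
    resolved: dict[tuple[str, int], str] = {}
    for pid, pair in solution.parent_haplotypes.items():
        for idx, hap in enumerate(pair):
            if hap.c is None:
                resolved[(pid, idx)] = C_UNKNOWN
    for oid, a in solution.assignments.items():
        if genotypes[oid].c_status != C_ABSENT_OBS or a.recombinant:
            continue
        mkey = (solution.family.mother, a.maternal_index)
        if mkey in resolved:
            resolved[mkey] = C_ABSENT
        if a.paternal_parent is not None:
            pkey = (a.paternal_parent, a.paternal_index)
            if pkey in resolved:
                resolved[pkey] = C_ABSENT
    return resolved


def apply_hemizygosity(
    solution: PhasingSolution, genotypes: Mapping[str, MHCGenotype]
) -> PhasingSolution:
    """Return a copy of the solution with resolved C-slot states."""
    resolved = infer_hemizygosity(solution, genotypes)
    new_parents = {}
    for pid, pair in solution.parent_haplotypes.items():
        new_pair = []
        for idx, hap in enumerate(pair):
            state = resolved.get((pid, idx))
            if state is not None and hap.c is None:
                hap = replace(hap, c_state=state)
            new_pair.append(hap)
        new_parents[pid] = tuple(new_pair)
    return replace(solution, parent_haplotypes=new_parents)


# ---------------------------------------------------------------------------
# linkage expectation


def expected_diplotype_count(
    parent1: Sequence[tuple[str, str]],
    parent2: Sequence[tuple[str, str]],
    linkage: str = "independent",
) -> int:
    """Number of distinct offspring gamete combinations for two parents.

    Each parent is a per-locus list of allele pairs (the pair order defines
    the phase used under complete linkage). Under independent assortment a
    parent's gametes are the cross-product of its per-locus alleles; under
    complete linkage only the two parental haplotypes are transmitted.
    """
    if linkage not in ("independent", "complete"):
        raise ValueError(f"linkage must be 'independent' or 'complete': {linkage!r}")
    if len(parent1) != len(parent2):
        raise ValueError("parents must be given the same number of loci")

    def gametes(parent: Sequence[tuple[str, str]]) -> set[tuple[str, ...]]:
        if linkage == "independent":
            return set(itertools.product(*(tuple(p) for p in parent)))
        return {
            tuple(p[0] for p in parent),
            tuple(p[1] for p in parent),
        }

    g1, g2 = gametes(parent1), gametes(parent2)
    return len({tuple(sorted((a, b))) for a in g1 for b in g2})


# ---------------------------------------------------------------------------
# catalog


@dataclass
class CatalogEntry:
    haplotype_id: str
    haplotype: Haplotype
    composition_class: str
    sources: list[tuple[str, str]]  # (family id, parent id or "father*")
    n_offspring: int


@dataclass
class HaplotypeCatalog:
    entries: list[CatalogEntry]

    def __len__(self) -> int:
        return len(self.entries)

    def class_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for e in self.entries:
            out[e.composition_class] = out.get(e.composition_class, 0) + 1
        return out


def composition_class(hap: Haplotype, lineage_of: Mapping[str, str]) -> str:
    lineages = {lineage_of[a] for a in hap.alleles}
    if lineages == {"A", "B"}:
        return "AB"
    if lineages == {"A", "C"}:
        return "AC"
    if lineages == {"B", "C"}:
        return "BC"
    if lineages == {"B"}:
        return "B-only"
    if lineages == {"A"}:
        return "A-only"
    return "other"


def build_catalog(
    solutions: Iterable[PhasingSolution],
    lineage_of: Mapping[str, str],
    min_offspring: int = 5,
) -> HaplotypeCatalog:
    """Unique haplotypes (by allele content) across family solutions.

    Haplotypes of sampled parents enter the catalog when the parent has at
    least ``min_offspring`` assigned offspring in total (across families —
    fathers may sire offspring of several mothers). Inferred haplotypes of
    unsampled fathers enter when observed in at least ``min_offspring``
    offspring.
    """
    solutions = list(solutions)
    parent_counts: dict[str, int] = {}
    for sol in solutions:
        for pid, n in _parent_offspring_counts(sol).items():
            parent_counts[pid] = parent_counts.get(pid, 0) + n

    order: list[tuple] = []
    haps: dict[tuple, Haplotype] = {}
    sources: dict[tuple, list[tuple[str, str]]] = {}
    counts: dict[tuple, int] = {}

    def add(hap: Haplotype, fam: str, source: str, n: int) -> None:
        key = hap.key
        if key not in haps:
            order.append(key)
            haps[key] = hap
            sources[key] = []
            counts[key] = 0
        if (fam, source) not in sources[key]:
            sources[key].append((fam, source))
        counts[key] += n

    for sol in solutions:
        fam = sol.family.family_id or sol.family.mother
        per_parent_hap_counts: dict[tuple[str, int], int] = {}
        for a in sol.assignments.values():
            mk = (sol.family.mother, a.maternal_index)
            per_parent_hap_counts[mk] = per_parent_hap_counts.get(mk, 0) + 1
            if a.paternal_parent is not None:
                pk = (a.paternal_parent, a.paternal_index)
                per_parent_hap_counts[pk] = per_parent_hap_counts.get(pk, 0) + 1
        for pid, pair in sol.parent_haplotypes.items():
            if parent_counts.get(pid, 0) < min_offspring:
                continue
            for idx, hap in enumerate(pair):
                add(hap, fam, pid, per_parent_hap_counts.get((pid, idx), 0))
        for _, (hap, n) in sorted(sol.external_haplotype_counts().items()):
            if n >= min_offspring:
                add(hap, fam, "father*", n)

    entries = [
        CatalogEntry(
            haplotype_id=f"H{i + 1}",
            haplotype=haps[key],
            composition_class=composition_class(haps[key], lineage_of),
            sources=sources[key],
            n_offspring=counts[key],
        )
        for i, key in enumerate(order)
    ]
    return HaplotypeCatalog(entries)


# ---------------------------------------------------------------------------
# architecture checks


@dataclass
class ArchitectureReport:
    max_counts: dict[str, int]
    violations: list[str]
    correlations: dict[tuple[str, str], tuple[float, float]]  # rho, p

    @property
    def empty(self) -> bool:
        return not self.max_counts


def architecture_checks(
    genotypes: Iterable[MHCGenotype], lineage_of: Mapping[str, str]
) -> ArchitectureReport:
    """Population-level allele-count constraints of the capacity model:
    per individual, A <= 2, C <= 2 and A+B <= 4, with rank correlations of
    per-individual counts between lineage pairs."""
    rows = []
    violations = []
    for g in genotypes:
        n = {"A": 0, "B": 0, "C": len(g.c)}
        for a in g.ab:
            n[lineage_of[a]] += 1
        rows.append(n)
        if n["A"] > 2:
            violations.append(f"{g.individual}: {n['A']} lineage-A alleles (max 2)")
        if n["C"] > 2:
            violations.append(f"{g.individual}: {n['C']} lineage-C alleles (max 2)")
        if n["A"] + n["B"] > 4:
            violations.append(
                f"{g.individual}: {n['A'] + n['B']} A+B alleles (max 4)")
    if not rows:
        return ArchitectureReport({}, [], {})
    max_counts = {
        lin: max(r[lin] for r in rows) for lin in ("A", "B", "C")
    }
    correlations = {}
    for l1, l2 in (("C", "A"), ("C", "B"), ("A", "B")):
        x = [r[l1] for r in rows]
        y = [r[l2] for r in rows]
        if len(set(x)) > 1 and len(set(y)) > 1:
            rho, p = stats.spearmanr(x, y)
            correlations[(l1, l2)] = (float(rho), float(p))
    return ArchitectureReport(max_counts, violations, correlations)


# ---------------------------------------------------------------------------
# family congruence


@dataclass
class CongruenceRecord:
    offspring: str
    congruent: bool
    offending_alleles: list[str]
    alternative_fathers: list[str]


@dataclass
class CongruenceReport:
    records: list[CongruenceRecord]

    @property
    def fraction_congruent(self) -> float:
        if not self.records:
            return float("nan")
        return sum(r.congruent for r in self.records) / len(self.records)


def check_family_congruence(
    families: Iterable[PedigreeFamily],
    genotypes: Mapping[str, MHCGenotype],
    candidate_fathers: Sequence[str] | None = None,
) -> CongruenceReport:
    """Is each offspring's allele set the union of one valid haplotype from
    each assigned parent? Incongruent offspring are reported with the alleles
    neither parent carries, and with alternative fathers (from the candidate
    list) that would explain them — supporting mislabel/reassignment review.
    """
    families = list(families)
    if candidate_fathers is None:
        candidate_fathers = sorted(
            {f for fam in families for f in fam.fathers})

    hap_cache: dict[str, list[Haplotype]] = {}

    def haps(pid: str) -> list[Haplotype]:
        if pid not in hap_cache:
            uniq: dict[tuple, Haplotype] = {}
            for pair in enumerate_bipartitions(genotypes[pid]):
                for h in pair:
                    uniq[h.key] = h
            hap_cache[pid] = list(uniq.values())
        return hap_cache[pid]

    def explains(off: MHCGenotype, mother: str, father: str) -> bool:
        return any(
            union_explains(off, mh, ph)
            for mh in haps(mother)
            for ph in haps(father)
        )

    records = []
    for fam in families:
        for oid in fam.offspring:
            off = genotypes[oid]
            ok = any(explains(off, fam.mother, f) for f in fam.fathers
                     if f in genotypes)
            offending: list[str] = []
            alternatives: list[str] = []
            if not ok:
                parental = genotypes[fam.mother].alleles | frozenset().union(
                    *(genotypes[f].alleles for f in fam.fathers if f in genotypes),
                    frozenset(),
                )
                offending = sorted(off.alleles - parental)
                alternatives = [
                    f
                    for f in candidate_fathers
                    if f in genotypes
                    and f not in fam.fathers
                    and explains(off, fam.mother, f)
                ]
            records.append(CongruenceRecord(oid, ok, offending, alternatives))
    return CongruenceReport(records)
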