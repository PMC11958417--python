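"""Synthetic-data generator with known ground truth for the whole pipeline.

Emulates the study system end to end: a three-lineage exon-2 allele pool
(A: 5, B: 20, C: 4 alleles by default, between-lineage divergence well above
within-lineage divergence), haplotypes of one or two alleles whose optional
lineage-C slot may be truly absent (hemizygosity), mother-defined families
with Dirichlet-weighted multiple paternity, amplicon read tables with
injected chimeras, single-bp errors and cross-sample bleed-through plus
C-amplicon dropout, and co-dominant microsatellite genotypes.

Every draw flows from one ``numpy`` Generator seeded by ``SimConfig.seed``,
so identical configs give identical datasets, and the generator writes the
same in-memory objects (and, through :mod:`mhc_hapseg.io`, the same file
formats) the pipeline consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .filtering import PRIMER_AB, PRIMER_C, ASVTable
from .parentage import MicrosatGenotype
from .phasing import (
    C_ABSENT,
    C_ABSENT_OBS,
    C_PRESENT,
    Haplotype,
    MHCGenotype,
    PedigreeFamily,
)

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    seed: int = 0
    # allele pool (study counts: 5 A, 20 B, 4 C)
    pool_sizes: dict[str, int] = field(
        default_factory=lambda: {"A": 5, "B": 20, "C": 4})
    seq_length: int = 240
    within_divergence: float = 0.03
    between_divergence: float = 0.20
    # haplotype architecture
    ab_capacity: int = 2
    c_capacity: int = 1
    n_haplotypes: int = 14
    c_absent_fraction: float = 0.58  # ~ sqrt(0.34): 34% of offspring lack C
    # pedigree (study group 2 layout)
    n_mothers: int = 4
    n_fathers: int = 3
    offspring_per_mother: int = 10
    paternity_concentration: float = 1.0
    # sequencing
    read_depth: int = 2000
    chimera_rate: float = 0.05
    single_bp_rate: float = 0.05
    bleed_rate: float = 0.02
    c_dropout: float = 0.34  # 26 of 76 individuals failed C amplification
    replicate_fraction: float = 0.2
    # microsatellites
    n_microsat_loci: int = 11
    microsat_alleles_per_locus: int = 6
    microsat_error_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("within_divergence", "between_divergence",
                     "c_absent_fraction", "chimera_rate", "single_bp_rate",
                     "bleed_rate", "c_dropout", "replicate_fraction",
                     "microsat_error_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if any(n < 1 for n in self.pool_sizes.values()):
            raise ValueError("pool sizes must be >= 1")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class ArtifactRecord:
    variant: str
    amplicon: str
    kind: str  # chimera | single_bp | bleed
    parents: tuple[str, ...]


@dataclass
class SimTruth:
    config: SimConfig
    alleles: dict[str, str]
    lineage_of: dict[str, str]
    haplotype_pool: list[Haplotype]
    diplotypes: dict[str, tuple[Haplotype, Haplotype]]
    genotypes: dict[str, MHCGenotype]
    families: list[PedigreeFamily]
    parents_of: dict[str, tuple[str, str]]  # offspring -> (mother, father)
    transmitted: dict[str, tuple[Haplotype, Haplotype]]
    artifact_log: list[ArtifactRecord] = field(default_factory=list)
    c_dropout_samples: list[str] = field(default_factory=list)
    microsats: dict[str, MicrosatGenotype] = field(default_factory=dict)


_STOPS = {"TAA", "TAG", "TGA"}


def _fix_stops(seq: str) -> str:
    """Recode any in-frame stop codon (frame 0) so simulated exon alleles
    stay translatable."""
    codons = [seq[i:i + 3] for i in range(0, len(seq) - len(seq) % 3, 3)]
    fixed = [("C" + c[1:]) if c in _STOPS else c for c in codons]
    return "".join(fixed) + seq[len(codons) * 3:]


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    arr = np.array(list(seq))
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hits:
        arr[i] = rng.choice([b for b in "ACGT" if b != arr[i]])
    return "".join(arr)


def simulate_allele_pool(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, str], dict[str, str]]:
    """Three-lineage allele pool: each lineage descends from an ancestor
    diverged from a common base at the between-lineage rate, with alleles
    diverged from their ancestor at the within-lineage rate."""
    if cfg.within_divergence >= cfg.between_divergence:
        raise ValueError("within-lineage divergence must be below "
                         "between-lineage divergence")
    rng = rng if rng is not None else cfg.rng()
    base = _random_seq(rng, cfg.seq_length)
    alleles: dict[str, str] = {}
    lineage_of: dict[str, str] = {}
    for lineage in sorted(cfg.pool_sizes):
        ancestor = _mutate(rng, base, cfg.between_divergence)
        for i in range(cfg.pool_sizes[lineage]):
            name = f"{lineage}{i + 1:02d}"
            while True:
                seq = _fix_stops(_mutate(rng, ancestor, cfg.within_divergence))
                if seq not in alleles.values():
                    break
            alleles[name] = seq
            lineage_of[name] = lineage
    return alleles, lineage_of


def simulate_haplotype_pool(
    lineage_of: Mapping[str, str],
    cfg: SimConfig,
    rng: np.random.Generator,
) -> list[Haplotype]:
    """Haplotypes of 1-2 alleles; the C slot is filled with probability
    ``1 - c_absent_fraction`` (an empty slot is a true gene absence)."""
    ab_alleles = sorted(a for a, l in lineage_of.items() if l in "AB")
    c_alleles = sorted(a for a, l in lineage_of.items() if l == "C")
    pool: list[Haplotype] = []
    seen: set[tuple] = set()
    while len(pool) < cfg.n_haplotypes:
        has_c = rng.random() >= cfg.c_absent_fraction and c_alleles
        if has_c:
            c = str(rng.choice(c_alleles))
            n_ab = 1
        else:
            c = None
            n_ab = int(rng.choice([1, 2], p=[0.2, 0.8]))
        ab = tuple(sorted(rng.choice(ab_alleles, size=n_ab, replace=False)))
        hap = Haplotype(ab, c, "unknown" if c else C_ABSENT)
        if hap.key in seen:
            continue
        seen.add(hap.key)
        pool.append(hap)
    return pool


def _genotype_from(ind: str, h1: Haplotype, h2: Haplotype) -> MHCGenotype:
    ab = frozenset(h1.ab) | frozenset(h2.ab)
    c = frozenset(x for x in (h1.c, h2.c) if x)
    return MHCGenotype(
        individual=ind,
        ab=ab,
        c=c,
        c_status=C_PRESENT if c else C_ABSENT_OBS,
    )


def simulate_pedigree(cfg: SimConfig, rng: np.random.Generator | None = None,
                      haplotype_pool: list[Haplotype] | None = None) -> SimTruth:
    """Mother-defined families with Dirichlet-weighted multiple paternity.

    Each offspring's diplotype is the union of one transmitted haplotype per
    parent; no recombination is ever simulated.
    """
    rng = rng if rng is not None else cfg.rng()
    alleles, lineage_of = simulate_allele_pool(cfg, rng)
    pool = haplotype_pool or simulate_haplotype_pool(lineage_of, cfg, rng)

    diplotypes: dict[str, tuple[Haplotype, Haplotype]] = {}
    genotypes: dict[str, MHCGenotype] = {}

    def draw_pair() -> tuple[Haplotype, Haplotype]:
        i, j = rng.choice(len(pool), size=2, replace=False)
        return pool[i], pool[j]

    mothers = [f"M{i + 1}" for i in range(cfg.n_mothers)]
    fathers = [f"F{i + 1}" for i in range(cfg.n_fathers)]
    for ind in mothers + fathers:
        diplotypes[ind] = draw_pair()
        genotypes[ind] = _genotype_from(ind, *diplotypes[ind])

    families: list[PedigreeFamily] = []
    parents_of: dict[str, tuple[str, str]] = {}
    transmitted: dict[str, tuple[Haplotype, Haplotype]] = {}
    for mi, mid in enumerate(mothers):
        weights = rng.dirichlet(
            np.full(cfg.n_fathers, cfg.paternity_concentration))
        kids = []
        sires: set[str] = set()
        for k in range(cfg.offspring_per_mother):
            oid = f"{mid}-O{k + 1}"
            fid = fathers[int(rng.choice(cfg.n_fathers, p=weights))]
            mh = diplotypes[mid][int(rng.integers(2))]
            fh = diplotypes[fid][int(rng.integers(2))]
            diplotypes[oid] = (mh, fh)
            genotypes[oid] = _genotype_from(oid, mh, fh)
            parents_of[oid] = (mid, fid)
            transmitted[oid] = (mh, fh)
            sires.add(fid)
            kids.append(oid)
        families.append(
            PedigreeFamily(
                mother=mid, offspring=kids, fathers=sorted(sires),
                family_id=f"fam{mi + 1}"))
    return SimTruth(
        config=cfg,
        alleles=alleles,
        lineage_of=lineage_of,
        haplotype_pool=pool,
        diplotypes=diplotypes,
        genotypes=genotypes,
        families=families,
        parents_of=parents_of,
        transmitted=transmitted,
    )


def inject_recombinant(truth: SimTruth, rng: np.random.Generator | None = None
                       ) -> str | None:
    """Replace one offspring's maternal transmission with a single
    A/B-vs-C-boundary exchange of the mother's two haplotypes.

    The injection is chosen to be detectable: the exchanged C allele must
    not be carried by any father of the family (so no plain explanation can
    absorb it) and both maternal haplotypes must be transmitted to other
    offspring (so the mother's phase stays pinned). Returns the offspring
    id, or None if no such injection exists.
    """
    rng = rng if rng is not None else np.random.default_rng(truth.config.seed + 1)
    for fam in truth.families:
        h1, h2 = truth.diplotypes[fam.mother]
        for donor_ab, donor_c in ((h1, h2), (h2, h1)):
            if donor_c.c is None or donor_ab.c == donor_c.c:
                continue
            if any(donor_c.c in truth.genotypes[f].c for f in fam.fathers):
                continue
            rec = Haplotype(donor_ab.ab, donor_c.c, donor_c.c_state)
            if rec.key in (h1.key, h2.key):
                continue
            # candidate offspring: received donor_ab; leave others pinning
            # both maternal haplotypes
            candidates = [
                o for o in fam.offspring
                if truth.transmitted[o][0].key == donor_ab.key
            ]
            others = [o for o in fam.offspring if o not in candidates]
            pinned_c = any(
                truth.transmitted[o][0].key == donor_c.key for o in others)
            if len(candidates) < 2 or not pinned_c:
                continue
            oid = candidates[int(rng.integers(len(candidates)))]
            _, fh = truth.transmitted[oid]
            truth.transmitted[oid] = (rec, fh)
            truth.diplotypes[oid] = (rec, fh)
            truth.genotypes[oid] = _genotype_from(oid, rec, fh)
            return oid
    return None


def _mutate_one(rng: np.random.Generator, seq: str) -> str:
    i = int(rng.integers(len(seq)))
    return seq[:i] + str(rng.choice([b for b in "ACGT" if b != seq[i]])) + seq[i + 1:]


def simulate_asv_table(
    truth: SimTruth,
    cfg: SimConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[ASVTable, list[ArtifactRecord]]:
    """Amplicon read table for every individual, with injected artifacts.

    Per sample the A/B primer set amplifies the A and B alleles and the C
    primer set the C alleles; a C-less individual still yields a C amplicon
    of off-target background reads (so a passed-but-empty C amplicon is
    observably "absent"), unless the amplicon drops out entirely.
    """
    cfg = cfg or truth.config
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 17)
    decoy = _random_seq(rng, cfg.seq_length)  # off-target background

    seq_to_vid: dict[str, str] = {}
    variants: dict[str, str] = {}

    def vid_for(seq: str) -> str:
        if seq not in seq_to_vid:
            vid = f"V{len(seq_to_vid) + 1:04d}"
            seq_to_vid[seq] = vid
            variants[vid] = seq
        return seq_to_vid[seq]

    allele_seq = truth.alleles
    pool_seqs = set(allele_seq.values())
    columns: dict[str, dict[str, int]] = {}
    meta_rows: list[tuple[str, str, str, str]] = []
    log: list[ArtifactRecord] = []
    truth.c_dropout_samples = []

    samples = sorted(truth.genotypes)
    n_rep = int(round(cfg.replicate_fraction * len(samples)))
    replicated = set(samples[:n_rep])
    carried_by_any = set().union(
        *(g.alleles for g in truth.genotypes.values()))

    def make_amplicon(sample: str, primer: str, rep: str,
                      carried: list[str]) -> None:
        amp_id = f"{sample}.{'AB' if primer == PRIMER_AB else 'C'}.{rep}"
        reads: dict[str, int] = {}
        if carried:
            bias = rng.dirichlet(np.full(len(carried), 8.0))
            counts = rng.multinomial(cfg.read_depth, bias)
            for aid, n in zip(carried, counts):
                if n > 0:
                    reads[vid_for(allele_seq[aid])] = int(n)
        else:
            reads[vid_for(decoy)] = cfg.read_depth
        # chimera: single-breakpoint concatenation of two carried alleles
        if len(carried) >= 2 and rng.random() < cfg.chimera_rate:
            i, j = rng.choice(len(carried), size=2, replace=False)
            p1, p2 = allele_seq[carried[i]], allele_seq[carried[j]]
            k = int(rng.integers(1, cfg.seq_length))
            chim = p1[:k] + p2[k:]
            if chim not in pool_seqs and chim != p1 and chim != p2:
                n = max(1, int(cfg.read_depth * rng.uniform(0.02, 0.06)))
                v = vid_for(chim)
                reads[v] = reads.get(v, 0) + n
                log.append(ArtifactRecord(
                    v, amp_id, "chimera", (carried[i], carried[j])))
        # single-bp error off one carried allele
        if carried and rng.random() < cfg.single_bp_rate:
            src = carried[int(rng.integers(len(carried)))]
            err = _mutate_one(rng, allele_seq[src])
            if err not in pool_seqs:
                n = max(1, int(cfg.read_depth * rng.uniform(0.02, 0.06)))
                v = vid_for(err)
                reads[v] = reads.get(v, 0) + n
                log.append(ArtifactRecord(v, amp_id, "single_bp", (src,)))
        # cross-sample bleed-through: an allele carried by other co-sequenced
        # samples but not by this one
        if rng.random() < cfg.bleed_rate:
            lineages = "AB" if primer == PRIMER_AB else "C"
            foreign = sorted(
                a for a in carried_by_any
                if truth.lineage_of[a] in lineages and a not in carried
            )
            if foreign:
                src = foreign[int(rng.integers(len(foreign)))]
                n = max(1, int(cfg.read_depth * rng.uniform(0.012, 0.03)))
                v = vid_for(allele_seq[src])
                reads[v] = reads.get(v, 0) + n
                log.append(ArtifactRecord(v, amp_id, "bleed", (src,)))
        columns[amp_id] = reads
        meta_rows.append((amp_id, sample, primer, rep))

    for sample in samples:
        g = truth.genotypes[sample]
        reps = ["r1", "r2"] if sample in replicated else ["r1"]
        for rep in reps:
            make_amplicon(sample, PRIMER_AB, rep, sorted(g.ab))
        if rng.random() < cfg.c_dropout:
            truth.c_dropout_samples.append(sample)
        else:
            for rep in reps:
                make_amplicon(sample, PRIMER_C, rep, sorted(g.c))

    amp_ids = [m[0] for m in meta_rows]
    counts = pd.DataFrame(
        0, index=sorted(variants), columns=amp_ids, dtype=int)
    for amp_id, reads in columns.items():
        for v, n in reads.items():
            counts.loc[v, amp_id] = n
    meta = pd.DataFrame(
        meta_rows, columns=["amplicon_id", "sample_id", "primer_set",
                            "replicate_tag"],
    ).set_index("amplicon_id")
    table = ASVTable(variants, counts, meta)
    truth.artifact_log = log
    return table, log


def simulate_microsats(
    truth: SimTruth,
    cfg: SimConfig | None = None,
    rng: np.random.Generator | None = None,
) -> dict[str, MicrosatGenotype]:
    """Co-dominant microsatellite genotypes over the simulated pedigree:
    founders drawn from per-locus frequencies, offspring Mendelian, with an
    optional per-locus genotyping error (random Hardy-Weinberg redraw)."""
    cfg = cfg or truth.config
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 29)
    loci = [f"L{i + 1:02d}" for i in range(cfg.n_microsat_loci)]
    sizes = {
        locus: [100 + 2 * k for k in range(cfg.microsat_alleles_per_locus)]
        for locus in loci
    }
    freqs = {
        locus: rng.dirichlet(np.full(cfg.microsat_alleles_per_locus, 2.0))
        for locus in loci
    }

    def hw_draw(locus: str) -> tuple[int, int]:
        a, b = rng.choice(sizes[locus], size=2, p=freqs[locus])
        return int(a), int(b)

    out: dict[str, MicrosatGenotype] = {}
    founders = [i for i in truth.genotypes if i not in truth.parents_of]
    for ind in sorted(founders):
        out[ind] = MicrosatGenotype(
            ind, {locus: hw_draw(locus) for locus in loci})
    for oid in sorted(truth.parents_of):
        mid, fid = truth.parents_of[oid]
        loci_g: dict[str, tuple[int, int] | None] = {}
        for locus in loci:
            m = out[mid].loci[locus]
            f = out[fid].loci[locus]
            pair = (m[int(rng.integers(2))], f[int(rng.integers(2))])
            if rng.random() < cfg.microsat_error_rate:
                pair = hw_draw(locus)
            loci_g[locus] = (min(pair), max(pair))
        out[oid] = MicrosatGenotype(oid, loci_g)
    truth.microsats = out
    return out


def simulate_dataset(cfg: SimConfig) -> tuple[SimTruth, ASVTable]:
    """Convenience: pedigree + ASV table + microsatellites in one call."""
    truth = simulate_pedigree(cfg)
    table, _ = simulate_asv_table(truth, cfg)
    simulate_microsats(truth, cfg)
    return truth, table


def noise_free(cfg: SimConfig) -> SimConfig:
    """Copy of a config with every artifact channel switched off."""
    return replace(
        cfg, chimera_rate=0.0, single_bp_rate=0.0, bleed_rate=0.0,
        c_dropout=0.0, microsat_error_rate=0.0)
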