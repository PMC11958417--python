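# Methods

This note records the models, conventions and design choices behind
`mhc_hapseg`, in the order the pipeline runs them.

## Genetic architecture model

All phasing operates under one capacity model, chosen to encode the
architecture supported by the study system's family and population data:

* one composite **A/B region** holding up to `ab_capacity = 2` alleles per
  haplotype (lineages A and B segregate in the same loci; whether the region
  is one locus with two copies or two adjacent loci is left open — the
  capacity covers both readings);
* one **C locus** holding `c_capacity ∈ {0, 1}` alleles per haplotype; a
  chromosome may lack the gene entirely (hemizygosity).

Consequences used throughout: an individual carries at most 4 A+B alleles
and at most 2 C alleles; A-allele and B-allele counts compete for the same
four slots; a parent transmits exactly one of two haplotypes per offspring.
Capacities are constructor arguments, so the machinery is reusable for other
multigene families.

Genotypes are **presence-only**: amplicon data give no dosage, so an allele
may sit on both of a parent's haplotypes, and every enumeration includes
homozygous placements. The C slot of a haplotype carrying no C allele is a
three-state quantity: `allele` / `absent` (demonstrated gene absence) /
`unknown` (absence vs homozygosity unresolved).

## ASV filtering

Filters run in a fixed order — sample coverage, variant coverage,
off-target, per-amplicon frequency, artifact classification — with strict
(`<`) threshold comparisons so boundary values survive:

| parameter | default | meaning |
|---|---|---|
| `min_sample_coverage` | 100 reads | amplicons under this total are dropped |
| `min_variant_max_coverage` | 10 reads | variants whose maximum per-amplicon count is lower are dropped |
| `min_frequency` | 0.01 | per-amplicon frequency floor (flagging is per amplicon; a variant may stay a true allele elsewhere) |
| `offtarget_identity_floor` | 0.80 | best global-alignment identity to any reference below this discards the variant; the original analysis inspected alignments manually, so the floor is this package's own operationalisation |
| `cross_amplicon_minor_fraction` | 0.25 | bleed-through flag: in-amplicon frequency below this fraction of the variant's median frequency where it is true |
| `cross_amplicon_max_frequency` | 0.05 | bleed-through is a trace signal; occurrences at or above this frequency are never flagged. Without this ceiling, a true allele in a high-copy-number individual (four co-amplified alleles plus amplification bias can push one allele below 10% of its frequency in low-copy carriers) is misflagged |

Chimera detection considers single-breakpoint concatenations of two
co-occurring higher-frequency parents only; single-bp artifacts require a
co-occurring parent exactly one substitution away. Both searches are within
amplicon, matching the PCR mechanism that generates them. Replicate
discordance is reported, never auto-dropped.

Degenerate inputs: a table that empties out is a valid "no data" result,
not an exception; an empty reference panel for the off-target step is an
error.

## Lineage assignment

Diagnostic columns are derived from whatever lineage-labelled reference
alignment is supplied: a column is diagnostic for a lineage when it is
fixed within the lineage and no other reference carries that base. A query
matching all diagnostic columns of exactly one lineage is assigned by that
evidence; otherwise the nearest reference by nucleotide p-distance decides,
and an exact tie is reported `unassigned` rather than broken arbitrarily.
Assignment is at the lineage level only — A and B share loci, so locus-level
assignment would be meaningless. Phylogenetic-network evidence used
alongside diagnostic sites in the original analysis is replaced by the
nearest-reference rule: for well-separated lineages both draw the same
decision boundary, and the rule is deterministic and testable.

## Parentage

The LOD of a candidate parent is `Σ_loci ln[P(g_o | g_c parent) / P(g_o)]`
with transmission probabilities from Mendelian counting and `P(g_o)` from
Hardy–Weinberg at sample allele frequencies (counting estimator). The
genotyping-error model is a simple mixture: with probability `error_rate`
(default 0.01) the observed single-locus genotype is an unrelated
Hardy–Weinberg draw, so an incompatible locus contributes `ln(error_rate)`
instead of −∞. This replaces the full Cervus-style per-genotype error
algebra and simulation-based confidence (Delta), which are out of scope;
assignment instead requires a positive LOD and consistency between the
single-parent and parent-pair analyses. Two same-sex candidates with
positive LODs within 0.1 of each other make the offspring `ambiguous` —
such cases are resolved downstream by MHC congruence
(`check_family_congruence` suggests alternative compatible fathers).
Families are mother-defined because multiple paternity (with sperm storage)
is expected; the minimum number of unsampled fathers is
`ceil(max_locus |non-maternal alleles| / 2)`.

## Phasing

`phase_family` is an exact search. For each parent, every unordered pair of
capacity-valid haplotypes whose union equals the parent's allele set is
enumerated (including shared-allele placements; a single C allele generates
"on haplotype 1", "on haplotype 2" and homozygous options). Over the
product of parental bipartitions, an offspring is **explained** when its
allele set equals the union of one maternal and one paternal haplotype
(C ignored when the offspring's C observation is missing; for unsampled
fathers the set-difference remainder must itself be a valid haplotype).
The objective is lexicographic: maximise explained offspring, then minimise
recombinant transmissions. All co-optimal solutions are retained; the
lexicographically first (by sorted allele content) is returned with the
multiplicity count, so downstream consumers never see a silent arbitrary
pick. `phase_families` additionally reconciles fathers shared between
families: among each family's optima, bipartitions consistent across all
the father's families are preferred (a father whose second haplotype is
unobserved in one family is pinned by another).

For speed the search groups each father's bipartitions by their
offspring-explanation signature and iterates the product over signatures,
expanding back to concrete bipartitions only at the optimum; offspring
assignments are derived lazily. This changes nothing about the result —
the enumeration stays exhaustive.

**Recombination** is modelled as a single exchange between a parent's two
haplotypes at the A/B-vs-C boundary, the only boundary observable at this
marker resolution. Recombinant frequency = recombinant transmissions /
transmissions from eligible parents, where a parent is eligible with at
least `min_offspring = 5` assigned offspring and two haplotypes that differ
in their C slot (identical C content makes an exchange unobservable, since
lineage-specific C amplification guarantees full allelic coverage either
way). Inferred external (unsampled-father) haplotypes are never eligible.

**Hemizygosity**: a haplotype lacking a C allele is marked `absent` when at
least one non-recombinant offspring assigned that haplotype has C status
"absent" — the C amplicon worked and found nothing, and by the union rule
the other parental contribution also lacks C. Offspring with C status
"missing" (failed/absent amplicon) are never evidence. A parent whose
single C allele reached every offspring stays `unknown`: homozygosity and
hemizygosity cannot be told apart.

**Catalog**: haplotypes are unique by allele content (the resolved C state
is annotation, not identity). Parental haplotypes enter when the parent has
≥ 5 assigned offspring in total across families; external father haplotypes
when observed in ≥ 5 offspring. The composition class is the set of
lineages present ({A,B} → AB, {B} → B-only, …).

**Linkage expectation**: with two doubly-heterozygous parents,
`expected_diplotype_count` returns 16 distinct offspring combinations under
independent assortment (each parent's gametes are the cross-product of its
per-locus alleles) and 4 under complete linkage (each parent transmits one
of two haplotypes) — the contrast that motivates the whole segregation
analysis.

## Diversity metrics

* **p-distance** (nt and aa): differing sites / compared sites with
  pairwise deletion of gap and ambiguity columns; complete deletion is not
  offered because the study alleles are length-conserved. Unequal-length
  inputs are globally aligned first (match 1, mismatch −1, gap open −2,
  extend −1 — the same scores everywhere in the package).
* **Grantham model**: distances are derived from the published composition
  / polarity / volume residue table with α = 1.833, β = 0.1018,
  γ = 0.000399. The scaling ρ is calibrated at model build so that the mean
  of the 190 pairwise distances is exactly 100 (ρ ≈ 50.79). Recomputing the
  matrix from the formula reproduces the canonical extremes after rounding
  ((L,I) = 5, (C,W) = 215) but is known to differ from a few of the
  historically printed integers by ±1 (e.g. S–R evaluates to 109.4); the
  formula, not the printed table, is treated as the definition, and the
  test oracle is an independent evaluation of the same formula.
* **Functional distance**: mean Grantham units per compared site over the
  aligned translations — the per-site mean (not the sum) matches the
  magnitude of the study's per-haplotype values (≈ 15–37 on a 5–215
  matrix). Restriction to peptide-binding-region sites is available
  (`sites=` argument) but off by default, as the published per-haplotype
  values are consistent with all-site averaging. Internal stop codons are
  errors, never silently skipped.
* **UTR identity**: global alignment, identical columns / aligned columns,
  gaps counting as mismatches.

Within-haplotype records average over allele pairs; single-allele
haplotypes are undefined (reported NA) rather than zero. Metric
correlations are Pearson over defined records, requiring ≥ 3 records and
non-constant metrics.

## Synthetic data

The generator's defaults mirror the study conditions: allele pool of 5 A,
20 B and 4 C alleles; 4 mothers, 3 fathers, 10 offspring per mother; 11
microsatellite loci; C-amplicon dropout 0.34 (the observed fraction of
individuals without C amplification); C-absent haplotype fraction 0.58 ≈
√0.34, so that about a third of offspring lack a C allele under random
pairing. Within-lineage divergence 0.03 and between-lineage divergence 0.20
substitutions per site give cleanly separable lineages (between ≫ within);
sequences are built codon-aware so frame-0 translations exist. Artifact
channels (chimera 0.05, single-bp 0.05, bleed-through 0.02 per amplicon)
are realistic-magnitude defaults; bleed-through draws from alleles carried
by other co-sequenced samples, as real cross-contamination does. Multiple
paternity is parameterised by a Dirichlet concentration over fathers
(low → one dominant sire, high → even siring) rather than a fixed father
count. The simulator never recombines; `inject_recombinant` adds exactly
one detectable A/B-vs-C exchange (the moved C allele absent from all the
family's fathers, both maternal haplotypes pinned by other offspring), for
testing the recombinant counter.

What the generator does **not** emulate: read-level error profiles
(quality scores, PCR stochasticity beyond multinomial sampling), indels
(available as an off-target test option only), allele-specific
amplification failure of A/B alleles, and population structure in
microsatellite frequencies. Tests passing on simulated data therefore
validate the logic of filtering, assignment and phasing under the stated
architecture — not robustness to every artefact of a real sequencing run.

## Problem sizes and determinism

The test suite phases 240 simulated families (120 clean, 120 with 5%
C-observation dropout) with 2–4 fathers and 5–20 offspring each — sizes at
which the exact search and the recovery statistics are comfortably stable.
All randomness flows from explicit integer seeds (`numpy` Generators);
reruns are byte-identical, and the acceptance script's computation is exact,
so its output is seed-independent.

## Known limitations

* Parents with a missing C observation are phased with `unknown` C slots;
  an offspring C allele cannot be attributed to such a parent, which can
  leave offspring unexplained rather than guessed.
* Unsampled-father haplotypes are clustered by content only; the minimum
  father count `ceil(distinct remainders / 2)` ignores linkage between
  remainders across offspring.
* Underdetermined families (e.g. an offspring whose allele set equals the
  mother's full set, with no sampled father) are reported with
  multiplicity > 1; no tie is broken silently, and downstream counts use
  the canonical first optimum.
* The per-family recombination eligibility rule is evaluated per family;
  a father's offspring are not pooled across families for the
  five-offspring eligibility floor (they are pooled for catalog
  inclusion).
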