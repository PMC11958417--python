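"""Post-denoising filtering of MHC amplicon-sequence-variant (ASV) tables.

The pipeline consumes a variant x amplicon read-count table (the output of
an upstream denoiser) and applies, in a fixed order, the artifact filters
used for multigene MHC amplicon genotyping:

1. amplicons with total coverage below a floor are dropped, then variants
   whose maximum per-amplicon count is below a floor are dropped;
2. variants too divergent from any reference allele are discarded
   (off-target amplification);
3. variants below a per-amplicon frequency floor are flagged in that
   amplicon (a variant may remain a true allele elsewhere);
4. remaining low-frequency variants are classified as chimeras, single-bp
   PCR/sequencing errors (both must co-occur with higher-frequency parent
   sequences in the same amplicon) or cross-amplicon bleed-through
   (a variant at a small fraction of the frequency it shows in amplicons
   where it is a true allele).

Thresholds are strict "less than" comparisons; boundary values survive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .align import global_identity
from .phasing import C_ABSENT_OBS, C_MISSING, C_PRESENT, MHCGenotype

PRIMER_AB = "NF2-NR2"  # co-amplifies lineage A and B alleles
PRIMER_C = "DF2-DR2"  # amplifies lineage C alleles

TRUE_ALLELE = "true_allele"
ARTIFACT_CHIMERA = "artifact_chimera"
ARTIFACT_1BP = "artifact_1bp"
ARTIFACT_CROSS = "artifact_cross_amplicon"
LOW_FREQUENCY = "low_frequency"
LOW_COVERAGE = "low_coverage"
OFFTARGET = "offtarget"

STATES = (
    TRUE_ALLELE,
    ARTIFACT_CHIMERA,
    ARTIFACT_1BP,
    ARTIFACT_CROSS,
    LOW_FREQUENCY,
    LOW_COVERAGE,
    OFFTARGET,
)


@dataclass
class FilterConfig:
    min_sample_coverage: int = 100
    min_variant_max_coverage: int = 10
    min_frequency: float = 0.01
    offtarget_identity_floor: float = 0.80
    cross_amplicon_minor_fraction: float = 0.25
    # bleed-through is a trace signal: never flag occurrences at or above
    # this in-amplicon frequency (protects true alleles under amplification
    # bias in high-copy-number samples)
    cross_amplicon_max_frequency: float = 0.05
    detect_chimeras: bool = True
    detect_single_bp: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.min_frequency <= 1:
            raise ValueError("min_frequency must be in [0, 1]")
        for name in ("min_sample_coverage", "min_variant_max_coverage"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class ASVTable:
    """A variant x amplicon read-count table with amplicon metadata.

    ``variants`` maps variant id -> nucleotide sequence; ``counts`` is the
    integer matrix (index: variant ids, columns: amplicon ids); ``amplicons``
    (index: amplicon id) carries ``sample_id``, ``primer_set`` and
    ``replicate_tag`` columns.
    """

    variants: dict[str, str]
    counts: pd.DataFrame
    amplicons: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("negative read counts")
        if set(self.counts.index) != set(self.variants):
            raise ValueError("counts index and variant ids disagree")
        if set(self.counts.columns) != set(self.amplicons.index):
            raise ValueError("counts columns and amplicon metadata disagree")
        for col in ("sample_id", "primer_set"):
            if col not in self.amplicons.columns:
                raise ValueError(f"amplicon metadata lacks column {col!r}")
            if self.amplicons[col].isna().any():
                raise ValueError(f"amplicon metadata has missing {col!r}")
        seqs = list(self.variants.values())
        if any(not s for s in seqs):
            raise ValueError("empty variant sequence")
        if len(set(seqs)) != len(seqs):
            raise ValueError("duplicate variant sequences")
        self.counts = self.counts.astype(int)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_amplicons(self) -> int:
        return self.counts.shape[1]

    @property
    def empty(self) -> bool:
        return self.counts.size == 0

    def subset(
        self, variants: list[str] | None = None, amplicons: list[str] | None = None
    ) -> "ASVTable":
        v = list(variants) if variants is not None else list(self.counts.index)
        a = list(amplicons) if amplicons is not None else list(self.counts.columns)
        return ASVTable(
            {vid: self.variants[vid] for vid in v},
            self.counts.loc[v, a].copy(),
            self.amplicons.loc[a].copy(),
        )

    def frequencies(self) -> pd.DataFrame:
        totals = self.counts.sum(axis=0)
        return self.counts.div(totals.where(totals > 0, 1), axis=1)


@dataclass
class StatusTable:
    """Per-(variant, amplicon) classification with a free-text reason."""

    records: dict[tuple[str, str], tuple[str, str]] = field(default_factory=dict)
    dropped_amplicons: dict[str, str] = field(default_factory=dict)

    def mark(self, variant: str, amplicon: str, state: str, reason: str = "") -> None:
        if state not in STATES:
            raise ValueError(f"unknown state {state!r}")
        self.records[(variant, amplicon)] = (state, reason)

    def state_of(self, variant: str, amplicon: str) -> str | None:
        rec = self.records.get((variant, amplicon))
        return rec[0] if rec else None

    def merge(self, other: "StatusTable") -> None:
        self.records.update(other.records)
        self.dropped_amplicons.update(other.dropped_amplicons)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (v, a, state, reason)
            for (v, a), (state, reason) in sorted(self.records.items())
        ]
        return pd.DataFrame(rows, columns=["variant", "amplicon", "state", "reason"])


def filter_by_coverage(
    table: ASVTable, cfg: FilterConfig
) -> tuple[ASVTable, StatusTable]:
    """Drop amplicons with total reads below the sample floor, then variants
    whose maximum per-amplicon count (after the drop) is below the variant
    floor. An empty survivor table is a valid "no data" result."""
    status = StatusTable()
    totals = table.counts.sum(axis=0)
    keep_amp = [a for a in table.counts.columns if totals[a] >= cfg.min_sample_coverage]
    for a in table.counts.columns:
        if a not in keep_amp:
            status.dropped_amplicons[a] = (
                f"total coverage {totals[a]} < {cfg.min_sample_coverage}")
    sub = table.subset(amplicons=keep_amp)
    if sub.counts.columns.empty:
        return sub.subset(variants=[]), status
    vmax = sub.counts.max(axis=1)
    keep_var = []
    for v in sub.counts.index:
        if vmax[v] < cfg.min_variant_max_coverage:
            for a in keep_amp:
                if sub.counts.loc[v, a] > 0:
                    status.mark(
                        v, a, LOW_COVERAGE,
                        f"max coverage {vmax[v]} < {cfg.min_variant_max_coverage}")
        else:
            keep_var.append(v)
    return sub.subset(variants=keep_var), status


def filter_offtarget(
    table: ASVTable, references: Mapping[str, str], cfg: FilterConfig
) -> tuple[ASVTable, StatusTable]:
    """Discard variants whose best global-alignment identity to every
    reference allele is below the off-target floor."""
    if not references:
        raise ValueError("empty reference set")
    status = StatusTable()
    ref_seqs = {s.upper() for s in references.values()}
    keep = []
    for vid, seq in table.variants.items():
        if seq.upper() in ref_seqs:
            keep.append(vid)
            continue
        best = max(global_identity(seq, r) for r in ref_seqs)
        if best < cfg.offtarget_identity_floor:
            for a in table.counts.columns:
                if table.counts.loc[vid, a] > 0:
                    status.mark(vid, a, OFFTARGET,
                                f"best identity {best:.3f} < "
                                f"{cfg.offtarget_identity_floor}")
        else:
            keep.append(vid)
    return table.subset(variants=keep), status


def filter_low_frequency(
    table: ASVTable, cfg: FilterConfig
) -> tuple[ASVTable, StatusTable]:
    """Flag variants below the per-amplicon frequency floor in that amplicon
    (strictly less than; exact-boundary variants survive). Counts of flagged
    cells are zeroed; variants left with no reads anywhere are dropped."""
    status = StatusTable()
    freqs = table.frequencies()
    counts = table.counts.copy()
    for a in counts.columns:
        for v in counts.index:
            if counts.loc[v, a] > 0 and freqs.loc[v, a] < cfg.min_frequency:
                status.mark(v, a, LOW_FREQUENCY,
                            f"frequency {freqs.loc[v, a]:.4f} < "
                            f"{cfg.min_frequency}")
                counts.loc[v, a] = 0
    keep = [v for v in counts.index if counts.loc[v].sum() > 0]
    out = ASVTable(
        {v: table.variants[v] for v in keep},
        counts.loc[keep],
        table.amplicons.copy(),
    )
    return out, status


def _hamming1(s1: str, s2: str) -> bool:
    if len(s1) != len(s2):
        return False
    diff = 0
    for a, b in zip(s1, s2):
        if a != b:
            diff += 1
            if diff > 1:
                return False
    return diff == 1


def _common_prefix(a: str, b: str) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            break
        n += 1
    return n


def _is_chimera(child: str, p1: str, p2: str) -> bool:
    """child == p1[:k] + p2[k:] for some internal breakpoint k."""
    if len(child) != len(p1) or len(child) != len(p2):
        return False
    lcp = _common_prefix(child, p1)
    lcs = _common_prefix(child[::-1], p2[::-1])
    length = len(child)
    k_min = max(1, length - lcs)
    k_max = min(length - 1, lcp)
    return k_min <= k_max


def classify_artifacts(table: ASVTable, cfg: FilterConfig) -> StatusTable:
    """Classify every (variant, amplicon) occurrence left after the coverage,
    off-target and frequency filters.

    In each amplicon a variant is an artifact when it co-occurs with
    higher-frequency parents that explain it (single-bp mismatch or
    single-breakpoint chimera), or when its in-amplicon frequency is a minor
    fraction of its frequency in the amplicons where it is a true allele
    (cross-amplicon bleed-through). Everything else is a true allele.
    """
    status = StatusTable()
    freqs = table.frequencies()
    seqs = table.variants
    within_flags: dict[tuple[str, str], tuple[str, str]] = {}

    for a in table.counts.columns:
        present = [v for v in table.counts.index if table.counts.loc[v, a] > 0]
        for v in present:
            fv = freqs.loc[v, a]
            parents = [u for u in present if u != v and freqs.loc[u, a] > fv]
            if cfg.detect_single_bp:
                hit = next(
                    (u for u in parents if _hamming1(seqs[v], seqs[u])), None)
                if hit is not None:
                    within_flags[(v, a)] = (
                        ARTIFACT_1BP, f"1 bp from {hit} "
                        f"({freqs.loc[hit, a]:.3f} > {fv:.3f})")
                    continue
            if cfg.detect_chimeras and len(parents) >= 2:
                found = None
                for u, w in ((x, y) for x in parents for y in parents if x != y):
                    if _is_chimera(seqs[v], seqs[u], seqs[w]):
                        found = (u, w)
                        break
                if found:
                    within_flags[(v, a)] = (
                        ARTIFACT_CHIMERA,
                        f"chimera of {found[0]} + {found[1]}")

    # provisional true occurrences -> cross-amplicon bleed-through test
    for v in table.counts.index:
        true_amps = [
            a for a in table.counts.columns
            if table.counts.loc[v, a] > 0 and (v, a) not in within_flags
        ]
        if not true_amps:
            continue
        ref_freqs = [freqs.loc[v, a] for a in true_amps]
        median = float(np.median(ref_freqs))
        for a in true_amps:
            fv = freqs.loc[v, a]
            if (fv < cfg.cross_amplicon_minor_fraction * median
                    and fv < cfg.cross_amplicon_max_frequency):
                status.mark(v, a, ARTIFACT_CROSS,
                            f"frequency {fv:.3f} < "
                            f"{cfg.cross_amplicon_minor_fraction} x median "
                            f"true frequency {median:.3f}")
            else:
                status.mark(v, a, TRUE_ALLELE, "")
    for (v, a), (state, reason) in within_flags.items():
        status.mark(v, a, state, reason)
    return status


@dataclass
class FilterResult:
    table: ASVTable
    status: StatusTable


def run_filter_chain(
    table: ASVTable,
    references: Mapping[str, str] | None,
    cfg: FilterConfig | None = None,
) -> FilterResult:
    """Apply the full filter chain in its fixed order: sample coverage ->
    variant max coverage -> off-target -> per-amplicon frequency -> artifact
    classification."""
    cfg = cfg or FilterConfig()
    status = StatusTable()
    table, s = filter_by_coverage(table, cfg)
    status.merge(s)
    if references:
        table, s = filter_offtarget(table, references, cfg)
        status.merge(s)
    table, s = filter_low_frequency(table, cfg)
    status.merge(s)
    status.merge(classify_artifacts(table, cfg))
    return FilterResult(table, status)


def call_genotypes(
    table: ASVTable,
    status: StatusTable,
    lineage_of: Mapping[str, str],
) -> dict[str, MHCGenotype]:
    """Aggregate true-allele calls per sample across its amplicons,
    replicates and primer sets.

    ``lineage_of`` maps variant id -> lineage (A/B/C). The lineage-C
    observation status is "missing" when a sample has no surviving C
    amplicon, "absent" when the C amplicon is present but yields no C
    allele.
    """
    per_sample_ab: dict[str, set[str]] = {}
    per_sample_c: dict[str, set[str]] = {}
    has_c_amplicon: dict[str, bool] = {}
    samples = list(dict.fromkeys(table.amplicons["sample_id"]))
    for s in samples:
        per_sample_ab[s] = set()
        per_sample_c[s] = set()
        has_c_amplicon[s] = False
    for a in table.counts.columns:
        sample = table.amplicons.loc[a, "sample_id"]
        primer = table.amplicons.loc[a, "primer_set"]
        if primer == PRIMER_C:
            has_c_amplicon[sample] = True
        for v in table.counts.index:
            if table.counts.loc[v, a] > 0 and status.state_of(v, a) == TRUE_ALLELE:
                lin = lineage_of.get(v)
                if lin == "C":
                    per_sample_c[sample].add(v)
                elif lin in ("A", "B"):
                    per_sample_ab[sample].add(v)
    out = {}
    for s in samples:
        if per_sample_c[s]:
            c_status = C_PRESENT
        elif has_c_amplicon[s]:
            c_status = C_ABSENT_OBS
        else:
            c_status = C_MISSING
        out[s] = MHCGenotype(
            individual=s,
            ab=frozenset(per_sample_ab[s]),
            c=frozenset(per_sample_c[s]),
            c_status=c_status,
        )
    return out


@dataclass
class ReplicateReport:
    n_pairs: int
    n_congruent: int
    discordances: list[tuple[str, str, list[str]]]  # amp1, amp2, sym-diff alleles

    @property
    def fraction_congruent(self) -> float:
        return self.n_congruent / self.n_pairs if self.n_pairs else float("nan")


def replicate_congruence(
    table: ASVTable,
    status: StatusTable,
    pairs: list[tuple[str, str]] | None = None,
) -> ReplicateReport:
    """Compare detected true-allele sets between replicate amplicons.

    Replicate pairs are derived from metadata (amplicons sharing sample and
    primer set, differing in replicate tag) unless given explicitly.
    Discordant pairs are reported, never auto-dropped.
    """
    def true_set(a: str) -> set[str]:
        return {
            v for v in table.counts.index
            if table.counts.loc[v, a] > 0 and status.state_of(v, a) == TRUE_ALLELE
        }

    if pairs is None:
        groups: dict[tuple[str, str], list[str]] = {}
        for a in table.counts.columns:
            key = (table.amplicons.loc[a, "sample_id"],
                   table.amplicons.loc[a, "primer_set"])
            groups.setdefault(key, []).append(a)
        pairs = [
            p
            for amps in groups.values()
            if len(amps) > 1
            for p in [tuple(sorted(amps)[:2])]
        ]
    else:
        known = set(table.counts.columns)
        for a1, a2 in pairs:
            if a1 not in known or a2 not in known:
                raise KeyError(f"unmatched replicate amplicon in pair ({a1}, {a2})")
    if not pairs:
        raise ValueError("no replicate pairs found")
    discordances = []
    n_ok = 0
    for a1, a2 in pairs:
        s1, s2 = true_set(a1), true_set(a2)
        if s1 == s2:
            n_ok += 1
        else:
            discordances.append((a1, a2, sorted(s1 ^ s2)))
    return ReplicateReport(len(pairs), n_ok, discordances)
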