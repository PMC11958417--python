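"""Readers and writers for every format the pipeline consumes or emits,
plus the end-to-end pipeline driver.

Sequence data travel as FASTA (``Bio.SeqIO``), count and result tables as
TSV, genotype-like tables as CSV, and configuration / summaries as JSON.
Allele lists inside a cell are comma-separated; missing values are "NA";
positional fields in any output are 1-based inclusive.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .diversity import HaplotypeDiversityRecord, metric_correlation
from .filtering import ASVTable, FilterConfig, StatusTable
from .lineage import Allele
from .parentage import MicrosatGenotype
from .phasing import (
    C_ABSENT_OBS,
    C_MISSING,
    C_PRESENT,
    HaplotypeCatalog,
    MHCGenotype,
    PedigreeFamily,
    PhasingSolution,
)

logger = logging.getLogger("mhc_hapseg")

NA = "NA"


class FormatError(ValueError):
    """A malformed input file, reported with file and line context."""


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path, default_lineage: str = "unassigned") -> list[Allele]:
    """Read an allele panel; a ``lineage=X`` token in the description sets
    the lineage. Duplicate ids are rejected."""
    alleles: list[Allele] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate allele id {rec.id!r}")
        seen.add(rec.id)
        lineage = default_lineage
        for token in rec.description.split():
            if token.startswith("lineage="):
                lineage = token.split("=", 1)[1]
        alleles.append(Allele(rec.id, str(rec.seq).upper(), lineage=lineage))
    if not alleles:
        raise FormatError(f"{path}: no FASTA records")
    return alleles


def write_fasta(path: str | Path, alleles: list[Allele]) -> None:
    records = [
        SeqRecord(Seq(a.nt_sequence), id=a.id,
                  description=f"lineage={a.lineage}")
        for a in alleles
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# ASV table + amplicon metadata


def read_asv_table(counts_path: str | Path, meta_path: str | Path) -> ASVTable:
    """TSV count table (variant_id, sequence, one column per amplicon) plus
    CSV amplicon metadata (amplicon_id, sample_id, primer_set,
    replicate_tag)."""
    raw = pd.read_csv(counts_path, sep="\t", dtype={"variant_id": str})
    for col in ("variant_id", "sequence"):
        if col not in raw.columns:
            raise FormatError(f"{counts_path}: missing column {col!r}")
    meta = pd.read_csv(meta_path, dtype=str)
    for col in ("amplicon_id", "sample_id", "primer_set", "replicate_tag"):
        if col not in meta.columns:
            raise FormatError(f"{meta_path}: missing column {col!r}")
    meta = meta.set_index("amplicon_id")
    amp_cols = [c for c in raw.columns if c not in ("variant_id", "sequence")]
    missing = [a for a in amp_cols if a not in meta.index]
    if missing:
        raise FormatError(
            f"{counts_path}: amplicon column(s) without metadata row: "
            f"{', '.join(missing)}")
    dup = raw["variant_id"][raw["variant_id"].duplicated()]
    if not dup.empty:
        first = dup.iloc[0]
        line = int(raw.index[raw["variant_id"] == first][1]) + 2
        raise FormatError(
            f"{counts_path}:{line}: duplicate variant id {first!r}")
    variants = dict(zip(raw["variant_id"], raw["sequence"].str.upper()))
    counts = raw.set_index("variant_id")[amp_cols].astype(int)
    return ASVTable(variants, counts, meta.loc[amp_cols])


def write_asv_table(
    table: ASVTable, counts_path: str | Path, meta_path: str | Path
) -> None:
    out = table.counts.copy()
    out.insert(0, "sequence", [table.variants[v] for v in out.index])
    out.index.name = "variant_id"
    out.reset_index().to_csv(counts_path, sep="\t", index=False)
    table.amplicons.reset_index(names="amplicon_id").to_csv(
        meta_path, index=False)


def write_status(status: StatusTable, path: str | Path) -> None:
    status.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# MHC genotypes


def write_mhc_genotypes(
    genotypes: Mapping[str, MHCGenotype], path: str | Path,
    lineage_of: Mapping[str, str] | None = None,
) -> None:
    rows = []
    for sid in sorted(genotypes):
        g = genotypes[sid]
        if lineage_of:
            a_alleles = sorted(x for x in g.ab if lineage_of.get(x) == "A")
            b_alleles = sorted(x for x in g.ab if lineage_of.get(x) == "B")
        else:
            a_alleles, b_alleles = sorted(g.ab), []
        rows.append((sid, "A", ",".join(a_alleles) or NA, "present"))
        rows.append((sid, "B", ",".join(b_alleles) or NA, "present"))
        rows.append((sid, "C", ",".join(sorted(g.c)) or NA, g.c_status))
    pd.DataFrame(
        rows, columns=["sample_id", "lineage", "alleles", "status"]
    ).to_csv(path, index=False)


def read_mhc_genotypes(
    path: str | Path,
) -> tuple[dict[str, MHCGenotype], dict[str, str]]:
    """Returns genotypes plus the allele -> lineage map implied by the
    table."""
    df = pd.read_csv(path, dtype=str)
    for col in ("sample_id", "lineage", "alleles", "status"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    lineage_of: dict[str, str] = {}
    per_sample: dict[str, dict] = {}
    for i, row in df.iterrows():
        sid, lin = row["sample_id"], row["lineage"]
        alleles = (
            [] if pd.isna(row["alleles"]) or row["alleles"] == NA
            else row["alleles"].split(","))
        slot = per_sample.setdefault(
            sid, {"ab": set(), "c": set(), "c_status": C_MISSING})
        for a in alleles:
            lineage_of[a] = lin
        if lin == "C":
            slot["c"].update(alleles)
            status = row["status"]
            if status not in (C_PRESENT, C_ABSENT_OBS, C_MISSING):
                raise FormatError(
                    f"{path}:{i + 2}: bad C status {status!r}")
            slot["c_status"] = status
        elif lin in ("A", "B"):
            slot["ab"].update(alleles)
        else:
            raise FormatError(f"{path}:{i + 2}: unknown lineage {lin!r}")
    genotypes = {
        sid: MHCGenotype(sid, frozenset(d["ab"]), frozenset(d["c"]),
                         d["c_status"])
        for sid, d in per_sample.items()
    }
    return genotypes, lineage_of


# ---------------------------------------------------------------------------
# families and microsatellites


def write_families(families: list[PedigreeFamily], path: str | Path) -> None:
    rows = [
        (f.family_id or f.mother, f.mother, ";".join(f.fathers) or NA,
         ";".join(f.offspring), "yes" if f.unknown_fathers else "no")
        for f in families
    ]
    pd.DataFrame(
        rows, columns=["family_id", "mother", "fathers", "offspring",
                       "unknown_fathers"],
    ).to_csv(path, index=False)


def read_families(path: str | Path) -> list[PedigreeFamily]:
    df = pd.read_csv(path, dtype=str)
    for col in ("family_id", "mother", "fathers", "offspring"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    out = []
    for _, row in df.iterrows():
        fathers = (
            [] if pd.isna(row["fathers"]) or row["fathers"] == NA
            else row["fathers"].split(";"))
        unknown = str(row.get("unknown_fathers", "no")).lower() in ("yes", "true")
        out.append(
            PedigreeFamily(
                mother=row["mother"],
                offspring=row["offspring"].split(";"),
                fathers=fathers,
                unknown_fathers=unknown,
                family_id=row["family_id"],
            )
        )
    return out


def write_microsats(
    genotypes: Mapping[str, MicrosatGenotype], path: str | Path
) -> None:
    rows = []
    for iid in sorted(genotypes):
        for locus, pair in sorted(genotypes[iid].loci.items()):
            if pair is None:
                rows.append((iid, locus, NA, NA))
            else:
                rows.append((iid, locus, pair[0], pair[1]))
    pd.DataFrame(
        rows, columns=["individual_id", "locus", "allele1", "allele2"]
    ).to_csv(path, index=False)


def read_microsats(path: str | Path) -> dict[str, MicrosatGenotype]:
    df = pd.read_csv(path, dtype={"individual_id": str, "locus": str})
    for col in ("individual_id", "locus", "allele1", "allele2"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    loci: dict[str, dict] = {}
    for _, row in df.iterrows():
        d = loci.setdefault(row["individual_id"], {})
        if str(row["allele1"]) in (NA, "nan") or pd.isna(row["allele1"]):
            d[row["locus"]] = None
        else:
            d[row["locus"]] = (int(row["allele1"]), int(row["allele2"]))
    return {iid: MicrosatGenotype(iid, d) for iid, d in loci.items()}


# ---------------------------------------------------------------------------
# results


def write_catalog(catalog: HaplotypeCatalog, path: str | Path) -> None:
    rows = []
    for e in catalog.entries:
        hap = e.haplotype
        alleles = ",".join(hap.ab + ((hap.c,) if hap.c else ()))
        rows.append(
            (e.haplotype_id, alleles, hap.c or NA,
             hap.c_state if hap.c is None else NA,
             e.composition_class,
             ";".join(f"{fam}:{src}" for fam, src in e.sources),
             e.n_offspring)
        )
    pd.DataFrame(
        rows,
        columns=["haplotype_id", "alleles", "c_allele", "c_state",
                 "composition_class", "sources", "n_offspring"],
    ).to_csv(path, sep="\t", index=False)


def write_assignments(
    solutions: Mapping[str, PhasingSolution], path: str | Path
) -> None:
    rows = []
    for fid in sorted(solutions):
        sol = solutions[fid]
        for oid in sol.family.offspring:
            a = sol.assignments.get(oid)
            if a is None:
                rows.append((fid, oid, NA, NA, NA, NA))
                continue
            mh = sol.parent_haplotypes[sol.family.mother][a.maternal_index]
            if a.paternal_parent is not None:
                ph = sol.parent_haplotypes[a.paternal_parent][a.paternal_index]
                src = a.paternal_parent
            else:
                ph = a.external
                src = "father*"
            rows.append(
                (fid, oid, ",".join(sorted(mh.alleles)), src,
                 ",".join(sorted(ph.alleles)),
                 "yes" if a.recombinant else "no"))
    pd.DataFrame(
        rows,
        columns=["family_id", "offspring", "maternal_haplotype",
                 "paternal_source", "paternal_haplotype", "recombinant"],
    ).to_csv(path, sep="\t", index=False)


def write_diversity(
    records: list[HaplotypeDiversityRecord], path: str | Path
) -> None:
    rows = [
        (r.haplotype_id,
         f"{r.nucl_p:.3f}" if r.defined else NA,
         f"{r.aa_p:.3f}" if r.defined else NA,
         f"{r.func_dist:.2f}" if r.defined else NA)
        for r in records
    ]
    pd.DataFrame(
        rows, columns=["haplotype_id", "nucl_p", "aa_p", "func_dist"]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class PipelineConfig:
    """Paths and stage parameters for the end-to-end run."""

    asv_counts: str | None = None
    asv_metadata: str | None = None
    references: str | None = None
    microsats: str | None = None
    families: str | None = None
    genotypes: str | None = None  # pre-called MHC genotypes (Sanger import)
    output_dir: str = "results"
    filter: FilterConfig = field(default_factory=FilterConfig)
    parentage_error_rate: float = 0.01
    min_offspring: int = 5
    seed: int = 0
    frame_offset: int = 0

    def __post_init__(self) -> None:
        if self.min_offspring < 1:
            raise ValueError("min_offspring must be >= 1")

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = json.load(fh)
        fcfg = FilterConfig(**raw.pop("filter", {}))
        return cls(filter=fcfg, **raw)


def run_pipeline(config: PipelineConfig) -> dict:
    """filter -> lineage -> parentage -> phase -> diversity.

    Stages run when their inputs are configured; results land in
    ``output_dir`` with a JSON summary. Raises on the first failing stage,
    keeping earlier outputs on disk.
    """
    from . import parentage as par
    from .diversity import haplotype_diversity
    from .filtering import call_genotypes, run_filter_chain
    from .lineage import assign_pool
    from .phasing import apply_hemizygosity, build_catalog, count_recombinants
    from .phasing import phase_families

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed}

    references = None
    if config.references:
        references = read_fasta(config.references)

    genotypes: dict[str, MHCGenotype] | None = None
    lineage_of: dict[str, str] = {}

    if config.asv_counts:
        logger.info("stage: filter")
        if not config.asv_metadata:
            raise FormatError("asv_counts given without asv_metadata")
        table = read_asv_table(config.asv_counts, config.asv_metadata)
        ref_map = {a.id: a.nt_sequence for a in references} if references else None
        result = run_filter_chain(table, ref_map, config.filter)
        write_status(result.status, out / "variant_status.tsv")
        logger.info("stage: lineage")
        # variants identical to a reference allele take its name
        ref_by_seq = (
            {a.nt_sequence.upper(): a.id for a in references}
            if references else {})
        rename = {
            vid: ref_by_seq.get(seq.upper(), vid)
            for vid, seq in result.table.variants.items()
        }
        allele_seqs = {
            rename[vid]: seq for vid, seq in result.table.variants.items()}
        if references:
            queries = [
                Allele(vid, seq) for vid, seq in result.table.variants.items()]
            assigned = assign_pool(queries, references)
            lineage_of = {
                rename[vid]: lin for vid, (lin, _) in assigned.items()}
            pd.DataFrame(
                [(rename[vid], lin, ev)
                 for vid, (lin, ev) in sorted(assigned.items())],
                columns=["allele_id", "lineage", "evidence"],
            ).to_csv(out / "lineages.csv", index=False)
        raw_genotypes = call_genotypes(
            result.table, result.status,
            {vid: lineage_of.get(rename[vid], "unassigned")
             for vid in result.table.variants})
        genotypes = {
            sid: MHCGenotype(
                sid,
                frozenset(rename[v] for v in g.ab),
                frozenset(rename[v] for v in g.c),
                g.c_status)
            for sid, g in raw_genotypes.items()
        }
        write_mhc_genotypes(genotypes, out / "mhc_genotypes.csv", lineage_of)
        summary["n_samples_genotyped"] = len(genotypes)
    elif config.genotypes:
        genotypes, lineage_of = read_mhc_genotypes(config.genotypes)

    families: list[PedigreeFamily] | None = None
    if config.families:
        families = read_families(config.families)
    elif config.microsats:
        logger.info("stage: parentage")
        msats = read_microsats(config.microsats)
        offspring = {k: v for k, v in msats.items() if k.count("-")}
        mothers = {k: v for k, v in msats.items()
                   if not k.count("-") and k.startswith("M")}
        fathers = {k: v for k, v in msats.items()
                   if not k.count("-") and k.startswith("F")}
        results, fams = par.assign_families(
            offspring, mothers, fathers,
            error_rate=config.parentage_error_rate)
        pd.DataFrame([asdict(r) for r in results]).to_csv(
            out / "parentage.csv", index=False)
        families = [
            PedigreeFamily(
                mother=f.mother, offspring=f.offspring, fathers=f.fathers,
                unknown_fathers=f.min_unsampled_fathers > 0,
                family_id=f"fam-{f.mother}")
            for f in fams
        ]
        write_families(families, out / "families.csv")
        summary["n_families"] = len(families)

    if families and genotypes:
        logger.info("stage: phase")
        solutions = phase_families(families, genotypes)
        solutions = {
            fid: apply_hemizygosity(sol, genotypes)
            for fid, sol in solutions.items()
        }
        catalog = build_catalog(
            solutions.values(), lineage_of, config.min_offspring)
        write_catalog(catalog, out / "haplotype_catalog.tsv")
        write_assignments(solutions, out / "offspring_assignments.tsv")
        rec = count_recombinants(solutions.values(), config.min_offspring)
        pd.DataFrame(
            [(";".join(rec.eligible_parents), rec.n_transmissions,
              rec.n_recombinant, rec.frequency)],
            columns=["eligible_parents", "n_transmissions", "n_recombinant",
                     "frequency"],
        ).to_csv(out / "recombination.tsv", sep="\t", index=False)
        summary["n_haplotypes"] = len(catalog)
        summary["composition_classes"] = catalog.class_counts()
        summary["n_recombinant"] = rec.n_recombinant

        if references:
            logger.info("stage: diversity")
            seqs = {a.id: a.nt_sequence for a in references}
            if config.asv_counts:
                seqs.update(allele_seqs)
            records = []
            for e in catalog.entries:
                alleles = list(e.haplotype.alleles)
                if not all(a in seqs for a in alleles):
                    continue
                try:
                    records.append(
                        haplotype_diversity(
                            e.haplotype_id, alleles, seqs,
                            frame_offset=config.frame_offset))
                except ValueError as exc:  # e.g. stop codon in frame
                    logger.warning("diversity skipped for %s: %s",
                                   e.haplotype_id, exc)
            if records:
                write_diversity(records, out / "diversity.tsv")
            defined = [r for r in records if r.defined]
            if len(defined) >= 3:
                corr = metric_correlation(records)
                corr.to_csv(out / "metric_correlation.tsv", sep="\t",
                            index=False)
                summary["min_metric_r2"] = float(corr["r2"].min())

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
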