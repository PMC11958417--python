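"""Bundled worked-example data: the published catshark family haplotypes.

The package ships the per-family MHC IIbeta haplotype table of the
*Scyliorhinus canicula* study system (five mother-defined families, fourteen
parental haplotypes, three within-haplotype distance metrics) and rebuilds
pedigree fixtures from it: each offspring's allele set is the union of one
maternal and one paternal haplotype, exactly as segregation-based phasing
assumes. Allele names are the study's allele numbers with their lineage
labels; sequence data are deposited externally and are not bundled, so the
distance columns carry the published values rather than recomputed ones.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .diversity import HaplotypeDiversityRecord
from .phasing import (
    C_ABSENT_OBS,
    C_PRESENT,
    Haplotype,
    MHCGenotype,
    PedigreeFamily,
)

_TABLE = "catshark_haplotypes.tsv"


def load_haplotype_table() -> pd.DataFrame:
    """The bundled per-family haplotype table (one row per haplotype)."""
    with resources.files("mhc_hapseg.data").joinpath(_TABLE).open() as fh:
        return pd.read_csv(fh, sep="\t", dtype={"group": str, "family": str})


def _parse_alleles(spec: str) -> tuple[tuple[str, ...], str | None, dict[str, str]]:
    ab: list[str] = []
    c: str | None = None
    lineages: dict[str, str] = {}
    for token in spec.split(","):
        allele, lineage = token.split(":")
        lineages[allele] = lineage
        if lineage == "C":
            c = allele
        else:
            ab.append(allele)
    return tuple(ab), c, lineages


def study_haplotypes() -> tuple[dict[str, Haplotype], dict[str, str]]:
    """Haplotypes keyed by their published ids, plus allele -> lineage."""
    table = load_haplotype_table()
    haps: dict[str, Haplotype] = {}
    lineage_of: dict[str, str] = {}
    for _, row in table.iterrows():
        ab, c, lineages = _parse_alleles(row["alleles"])
        lineage_of.update(lineages)
        haps[row["haplotype"]] = Haplotype(ab, c)
    return haps, lineage_of


def diversity_records() -> list[HaplotypeDiversityRecord]:
    """The published within-haplotype distance rows as diversity records
    (NA rows become undefined records)."""
    table = load_haplotype_table()
    records = []
    for _, row in table.iterrows():
        if pd.isna(row["nucl_p"]):
            records.append(HaplotypeDiversityRecord.undefined(row["haplotype"]))
        else:
            records.append(
                HaplotypeDiversityRecord(
                    row["haplotype"],
                    float(row["nucl_p"]),
                    float(row["aa_p"]),
                    float(row["func_dist"]),
                    True,
                )
            )
    return records


def _offspring_genotype(oid: str, hm: Haplotype, hp: Haplotype) -> MHCGenotype:
    ab = frozenset(hm.ab) | frozenset(hp.ab)
    c = frozenset(x for x in (hm.c, hp.c) if x)
    return MHCGenotype(
        oid, ab, c, C_PRESENT if c else C_ABSENT_OBS)


def _parent_genotype(pid: str, h1: Haplotype, h2: Haplotype) -> MHCGenotype:
    return _offspring_genotype(pid, h1, h2)


# Family #5 worked example: the mother-4 / father-1 / father-3 trio whose
# twelve offspring are unions of one haplotype per parent (father 2 sired a
# single offspring in this family and is excluded, as in the published
# reconstruction).
_FAMILY5_OFFSPRING: list[tuple[str, str, str, str]] = [
    ("1G2", "H9", "father1", "H11"),
    ("1B2", "H9", "father1", "H11"),
    ("1C4", "H9", "father1", "H12"),
    ("1H5", "H9", "father3", "H13"),
    ("2D1", "H10", "father1", "H11"),
    ("1J3", "H10", "father1", "H11"),
    ("1B6", "H10", "father1", "H11"),
    ("2C1", "H10", "father1", "H12"),
    ("2B9", "H10", "father3", "H13"),
    ("1A3", "H10", "father3", "H14"),
    ("1I10", "H10", "father3", "H14"),
    ("1J1", "H10", "father3", "H14"),
]

_PARENT_HAPS: dict[str, tuple[str, str]] = {
    "mother_g1": ("H1", "H2"),
    "mother1": ("H5", "H6"),
    "mother3": ("H7", "H8"),
    "mother4": ("H9", "H10"),
    "father1": ("H11", "H12"),
    "father3": ("H13", "H14"),
}

# parents excluded from the published catalog (fewer than five offspring);
# their haplotypes use alleles outside the catalog on purpose
_EXTRA_HAPS: dict[str, Haplotype] = {
    "M2a": Haplotype(("73", "74")),
    "M2b": Haplotype(("75",)),
    "F2a": Haplotype(("76", "77")),
    "F2b": Haplotype(("78",)),
}
_EXTRA_LINEAGES = {a: "B" for a in ("73", "74", "75", "76", "77", "78")}


def family5() -> tuple[PedigreeFamily, dict[str, MHCGenotype], dict[str, str]]:
    """The family #5 worked example: family, genotypes, allele lineages."""
    haps, lineage_of = study_haplotypes()
    genotypes = {
        pid: _parent_genotype(pid, haps[h1], haps[h2])
        for pid, (h1, h2) in _PARENT_HAPS.items()
        if pid in ("mother4", "father1", "father3")
    }
    offspring = []
    for oid, mh, _, ph in _FAMILY5_OFFSPRING:
        genotypes[oid] = _offspring_genotype(oid, haps[mh], haps[ph])
        offspring.append(oid)
    fam = PedigreeFamily(
        mother="mother4",
        offspring=offspring,
        fathers=["father1", "father3"],
        family_id="family5",
    )
    return fam, genotypes, lineage_of


def study_families() -> tuple[
    list[PedigreeFamily], dict[str, MHCGenotype], dict[str, str]
]:
    """All five families rebuilt from the haplotype table.

    Offspring allele sets are unions of one haplotype per parent, realising
    the per-haplotype offspring counts of the table (balanced where the
    maternal and paternal totals disagree because some sires fall below the
    catalog's five-offspring floor). Family #1's fathers are unsampled;
    families #3 and #5 include the below-threshold mother 2 and father 2.
    """
    haps, lineage_of = study_haplotypes()
    haps = {**haps, **_EXTRA_HAPS}
    lineage_of = {**lineage_of, **_EXTRA_LINEAGES}
    genotypes: dict[str, MHCGenotype] = {}
    for pid, (h1, h2) in _PARENT_HAPS.items():
        genotypes[pid] = _parent_genotype(pid, haps[h1], haps[h2])
    genotypes["mother2"] = _parent_genotype("mother2", haps["M2a"], haps["M2b"])
    genotypes["father2"] = _parent_genotype("father2", haps["F2a"], haps["F2b"])

    families: list[PedigreeFamily] = []

    def add_family(fid, mother, fathers, combos, unknown=False):
        offspring = []
        for i, (mh, ph) in enumerate(combos):
            oid = f"{fid}-o{i + 1:02d}"
            genotypes[oid] = _offspring_genotype(oid, haps[mh], haps[ph])
            offspring.append(oid)
        families.append(
            PedigreeFamily(
                mother=mother, offspring=offspring, fathers=fathers,
                unknown_fathers=unknown, family_id=fid))

    # family 1: 12 x H1 + 7 x H2 maternal transmissions, unsampled fathers
    maternal1 = ["H1"] * 12 + ["H2"] * 7
    paternal1 = ["H3" if i % 2 == 0 else "H4" for i in range(19)]
    add_family("family1", "mother_g1", [], list(zip(maternal1, paternal1)),
               unknown=True)

    # family 2: mother 1 with father 1 and father 3
    add_family(
        "family2", "mother1", ["father1", "father3"],
        [("H5", "H11"), ("H5", "H12"), ("H5", "H13"), ("H5", "H13"),
         ("H5", "H13"), ("H6", "H11"), ("H6", "H11"), ("H6", "H12"),
         ("H6", "H12"), ("H6", "H13"), ("H6", "H13")])

    # family 3: mother 2 (two offspring only), father 1
    add_family("family3", "mother2", ["father1"],
               [("M2a", "H12"), ("M2b", "H11")])

    # family 4: mother 3, father 1
    add_family(
        "family4", "mother3", ["father1"],
        [("H7", "H11"), ("H7", "H11"), ("H7", "H12"), ("H7", "H12"),
         ("H7", "H11"), ("H7", "H12"), ("H8", "H11"), ("H8", "H11"),
         ("H8", "H11"), ("H8", "H12"), ("H8", "H12")])

    # family 5: the worked example plus father 2's single offspring
    combos5 = [(mh, ph) for _, mh, _, ph in _FAMILY5_OFFSPRING]
    combos5.append(("H10", "F2a"))
    add_family("family5", "mother4", ["father1", "father2", "father3"], combos5)

    return families, genotypes, lineage_of
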