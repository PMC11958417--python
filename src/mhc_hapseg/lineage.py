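"""Assignment of MHC IIbeta alleles to allelic lineages A, B and C.

In *Scyliorhinus canicula* the exon-2 allele pool splits into three deeply
divergent clusters (lineages A-C). Lineages A and B segregate in the same
loci, so assignment is performed at the lineage level only, never at the
locus level. Two lines of evidence are combined: diagnostic alignment
columns that are fixed within one lineage and absent from the others, and
(as fallback) the nearest reference by nucleotide p-distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .align import align_pair
from .diversity import p_distance, translate

LINEAGES = ("A", "B", "C")
UNASSIGNED = "unassigned"


@dataclass
class Allele:
    """One MHC IIbeta exon-2 allele (e.g. ``Scca-DBB*17``)."""

    id: str
    nt_sequence: str
    frame_offset: int = 0
    lineage: str = UNASSIGNED

    @property
    def aa_sequence(self) -> str:
        return translate(self.nt_sequence, self.frame_offset)


@dataclass
class DiagnosticSiteSet:
    """Per lineage, alignment columns (0-based) fixed within the lineage and
    distinct from every other lineage in the reference alignment."""

    sites: dict[str, list[tuple[int, str]]] = field(default_factory=dict)

    def for_lineage(self, lineage: str) -> list[tuple[int, str]]:
        return self.sites.get(lineage, [])


def derive_diagnostic_sites(references: list[Allele]) -> DiagnosticSiteSet:
    """Scan a pre-aligned, lineage-labelled reference panel for columns where
    one lineage is fixed for a base that no other lineage carries."""
    if not references:
        raise ValueError("empty reference panel")
    lengths = {len(r.nt_sequence) for r in references}
    if len(lengths) != 1:
        raise ValueError("reference panel must be aligned to equal length")
    (length,) = lengths
    by_lineage: dict[str, list[Allele]] = {}
    for ref in references:
        by_lineage.setdefault(ref.lineage, []).append(ref)
    out = DiagnosticSiteSet()
    for lineage, members in by_lineage.items():
        cols: list[tuple[int, str]] = []
        others = [r for r in references if r.lineage != lineage]
        for col in range(length):
            bases = {r.nt_sequence[col].upper() for r in members}
            if len(bases) != 1:
                continue
            (base,) = bases
            if base == "-" or any(
                r.nt_sequence[col].upper() == base for r in others
            ):
                continue
            cols.append((col, base))
        if not cols:
            warnings.warn(
                f"no diagnostic column found for lineage {lineage}", stacklevel=2
            )
        out.sites[lineage] = cols
    return out


def _map_query_to_panel(query: str, template: str) -> dict[int, str]:
    """Map panel alignment columns to query bases via a global alignment of
    the query against one (gapped) panel reference."""
    ungapped = template.replace("-", "")
    row_t, row_q = align_pair(ungapped, query)
    # position in ungapped template -> query base (or '-')
    t_pos_to_q: dict[int, str] = {}
    t_pos = 0
    for a, b in zip(row_t, row_q):
        if a != "-":
            t_pos_to_q[t_pos] = b
            t_pos += 1
    col_to_q: dict[int, str] = {}
    u_pos = 0
    for col, base in enumerate(template):
        if base != "-":
            col_to_q[col] = t_pos_to_q.get(u_pos, "-").upper()
            u_pos += 1
    return col_to_q


def assign_lineage(
    query: Allele | str,
    references: list[Allele],
    sites: DiagnosticSiteSet | None = None,
) -> tuple[str, str]:
    """Assign a query allele to a lineage.

    Returns ``(lineage, evidence)``. Diagnostic sites are decisive when they
    unanimously support exactly one lineage; otherwise the nearest reference
    by nucleotide p-distance decides, and an exact tie between lineages
    yields ``unassigned`` with a warning.
    """
    if not references:
        raise ValueError("empty reference panel")
    seq = (query.nt_sequence if isinstance(query, Allele) else query).upper()
    if not seq:
        raise ValueError("empty query sequence")
    if sites is None:
        try:
            sites = derive_diagnostic_sites(references)
        except ValueError:
            sites = DiagnosticSiteSet()

    if sites.sites:
        panel_len = len(references[0].nt_sequence)
        if len(seq) == panel_len:
            col_to_q = {i: seq[i] for i in range(panel_len)}
        else:
            col_to_q = _map_query_to_panel(seq, references[0].nt_sequence)
        full_support = [
            lineage
            for lineage, cols in sites.sites.items()
            if cols and all(col_to_q.get(c) == b.upper() for c, b in cols)
        ]
        if len(full_support) == 1:
            return full_support[0], "diagnostic_sites"

    # nearest-reference fallback
    best: dict[str, float] = {}
    for ref in references:
        d = p_distance(seq, ref.nt_sequence.replace("-", ""), "nt")
        lin = ref.lineage
        if lin not in best or d < best[lin]:
            best[lin] = d
    ranked = sorted(best.items(), key=lambda kv: (kv[1], kv[0]))
    if len(ranked) > 1 and abs(ranked[0][1] - ranked[1][1]) < 1e-12:
        warnings.warn(
            f"query equidistant from lineages {ranked[0][0]} and {ranked[1][0]}",
            stacklevel=2,
        )
        return UNASSIGNED, "tie"
    return ranked[0][0], f"nearest_reference(p={ranked[0][1]:.4f})"


def assign_pool(
    queries: list[Allele], references: list[Allele]
) -> dict[str, tuple[str, str]]:
    """Assign every query allele; returns id -> (lineage, evidence)."""
    sites = derive_diagnostic_sites(references) if references else None
    out = {}
    for q in queries:
        lineage, evidence = assign_lineage(q, references, sites)
        q.lineage = lineage
        out[q.id] = (lineage, evidence)
    return out
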