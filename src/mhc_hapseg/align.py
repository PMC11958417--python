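"""Thin pairwise global-alignment helpers shared across the package.

All alignment in the pipeline (off-target screening, lineage queries, UTR
identity) goes through Biopython's ``PairwiseAligner`` in global mode with
one set of defaults: match 1, mismatch -1, gap open -2, gap extend -1.
"""

from __future__ import annotations

from functools import lru_cache

from Bio import Align

DEFAULT_MATCH = 1.0
DEFAULT_MISMATCH = -1.0
DEFAULT_OPEN = -2.0
DEFAULT_EXTEND = -1.0


def make_aligner(
    match: float = DEFAULT_MATCH,
    mismatch: float = DEFAULT_MISMATCH,
    open_gap: float = DEFAULT_OPEN,
    extend_gap: float = DEFAULT_EXTEND,
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = open_gap
    aligner.extend_gap_score = extend_gap
    return aligner


@lru_cache(maxsize=1)
def _default_aligner() -> Align.PairwiseAligner:
    return make_aligner()


def align_pair(
    seq1: str, seq2: str, aligner: Align.PairwiseAligner | None = None
) -> tuple[str, str]:
    """Globally align two sequences; return the two gapped rows.

    Deterministic: of co-optimal alignments the aligner's first is used.
    """
    if not seq1 or not seq2:
        raise ValueError("cannot align an empty sequence")
    aln = (aligner or _default_aligner()).align(seq1, seq2)[0]
    return str(aln[0]), str(aln[1])


def global_identity(
    seq1: str, seq2: str, aligner: Align.PairwiseAligner | None = None
) -> float:
    """Proportion of identical columns in the global alignment.

    Gap columns count as mismatches, so identity is matches / aligned length.
    """
    row1, row2 = align_pair(seq1, seq2, aligner)
    matches = sum(1 for a, b in zip(row1, row2) if a == b and a != "-")
    return matches / len(row1)
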