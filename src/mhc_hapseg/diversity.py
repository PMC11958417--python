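"""Within-haplotype sequence and functional diversity metrics.

Three distances summarise how different the alleles carried on one MHC IIbeta
haplotype are from each other:

* nucleotide p-distance — proportion of differing nucleotide sites,
* amino-acid p-distance — the same on the translated exon,
* functional distance — mean Grantham (1974) physicochemical distance per
  compared amino-acid site (the Pierini & Lenz convention of averaging the
  20x20 matrix over the alignment).

The Grantham matrix is not hard-coded: it is derived from the published
composition / polarity / volume residue properties with
``D_ij = rho * sqrt(alpha*dc^2 + beta*dp^2 + gamma*dv^2)``,
where ``rho`` is calibrated so the mean over the 190 residue pairs is 100.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy import stats

from .align import align_pair, make_aligner

# Grantham (1974) residue properties: composition c, polarity p, volume v.
GRANTHAM_PROPERTIES: dict[str, tuple[float, float, float]] = {
    "S": (1.42, 9.2, 32.0),
    "R": (0.65, 10.5, 124.0),
    "L": (0.0, 4.9, 111.0),
    "P": (0.39, 8.0, 32.5),
    "T": (0.71, 8.6, 61.0),
    "A": (0.0, 8.1, 31.0),
    "V": (0.0, 5.9, 84.0),
    "G": (0.74, 9.0, 3.0),
    "I": (0.0, 5.2, 111.0),
    "F": (0.0, 5.2, 132.0),
    "Y": (0.20, 6.2, 136.0),
    "C": (2.75, 5.5, 55.0),
    "H": (0.58, 10.4, 96.0),
    "Q": (0.89, 10.5, 85.0),
    "N": (1.33, 11.6, 56.0),
    "K": (0.33, 11.3, 119.0),
    "D": (1.38, 13.0, 54.0),
    "E": (0.92, 12.3, 83.0),
    "M": (0.0, 5.7, 105.0),
    "W": (0.13, 5.4, 170.0),
}

GRANTHAM_ALPHA = 1.833
GRANTHAM_BETA = 0.1018
GRANTHAM_GAMMA = 0.000399


@dataclass
class GranthamModel:
    """Physicochemical distance model over the 20 standard residues."""

    properties: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(GRANTHAM_PROPERTIES)
    )
    alpha: float = GRANTHAM_ALPHA
    beta: float = GRANTHAM_BETA
    gamma: float = GRANTHAM_GAMMA
    rho: float | None = None  # None: calibrate so the 190-pair mean is 100

    def __post_init__(self) -> None:
        residues = sorted(self.properties)
        raw = {}
        for r1, r2 in itertools.combinations(residues, 2):
            c1, p1, v1 = self.properties[r1]
            c2, p2, v2 = self.properties[r2]
            raw[(r1, r2)] = math.sqrt(
                self.alpha * (c1 - c2) ** 2
                + self.beta * (p1 - p2) ** 2
                + self.gamma * (v1 - v2) ** 2
            )
        if self.rho is None:
            self.rho = 100.0 / (sum(raw.values()) / len(raw))
        self._dist = {}
        for (r1, r2), d in raw.items():
            self._dist[(r1, r2)] = self._dist[(r2, r1)] = self.rho * d
        for r in residues:
            self._dist[(r, r)] = 0.0
        self.residues = residues

    def distance(self, res1: str, res2: str) -> float:
        try:
            return self._dist[(res1, res2)]
        except KeyError:
            raise KeyError(f"nonstandard residue pair ({res1!r}, {res2!r})") from None

    def matrix(self) -> pd.DataFrame:
        m = pd.DataFrame(
            [[self._dist[(a, b)] for b in self.residues] for a in self.residues],
            index=self.residues,
            columns=self.residues,
        )
        return m


_DEFAULT_MODEL: GranthamModel | None = None


def default_grantham_model() -> GranthamModel:
    global _DEFAULT_MODEL
    if _DEFAULT_MODEL is None:
        _DEFAULT_MODEL = GranthamModel()
    return _DEFAULT_MODEL


def grantham_pair(
    res1: str, res2: str, model: GranthamModel | None = None, *, on_nonstandard: str = "error"
) -> float | None:
    """Grantham distance between two residues (0 iff identical).

    ``on_nonstandard`` is ``"error"`` or ``"skip"`` (returns None).
    """
    model = model or default_grantham_model()
    try:
        return model.distance(res1.upper(), res2.upper())
    except KeyError:
        if on_nonstandard == "skip":
            return None
        raise


_NT = set("ACGT")
_AA = set(GRANTHAM_PROPERTIES)


def p_distance(seq1: str, seq2: str, mode: str = "nt") -> float:
    """Proportion of differing sites, with pairwise deletion of gap or
    ambiguity columns. Unequal-length inputs are globally aligned first."""
    if mode not in ("nt", "aa"):
        raise ValueError(f"mode must be 'nt' or 'aa', got {mode!r}")
    seq1, seq2 = seq1.upper(), seq2.upper()
    if len(seq1) != len(seq2):
        seq1, seq2 = align_pair(seq1, seq2)
    valid = _NT if mode == "nt" else _AA
    compared = diffs = 0
    for a, b in zip(seq1, seq2):
        if a in valid and b in valid:
            compared += 1
            if a != b:
                diffs += 1
    if compared == 0:
        raise ValueError("no comparable sites between the two sequences")
    return diffs / compared


def functional_distance(
    aa1: str,
    aa2: str,
    model: GranthamModel | None = None,
    *,
    sites: Iterable[int] | None = None,
) -> float:
    """Mean Grantham distance per compared site of two aligned proteins.

    Gap or nonstandard-residue columns are excluded from both the numerator
    and the site count. ``sites`` optionally restricts the computation to a
    subset of 0-based alignment columns (e.g. peptide-binding residues).
    """
    model = model or default_grantham_model()
    aa1, aa2 = aa1.upper(), aa2.upper()
    if len(aa1) != len(aa2):
        raise ValueError("protein sequences must be aligned to equal length")
    columns = range(len(aa1)) if sites is None else sites
    total = 0.0
    compared = 0
    for i in columns:
        a, b = aa1[i], aa2[i]
        if a in _AA and b in _AA:
            total += model.distance(a, b)
            compared += 1
    if compared == 0:
        raise ValueError("no comparable sites between the two proteins")
    return total / compared


def translate(nt_sequence: str, frame_offset: int = 0) -> str:
    """Translate an exon fragment; an internal stop codon is an error."""
    if frame_offset not in (0, 1, 2):
        raise ValueError("frame_offset must be 0, 1 or 2")
    coding = nt_sequence[frame_offset:]
    coding = coding[: len(coding) - len(coding) % 3]
    aa = str(Seq(coding).translate())
    if "*" in aa:
        raise ValueError("stop codon inside the amplified exon fragment")
    return aa


@dataclass
class HaplotypeDiversityRecord:
    haplotype_id: str
    nucl_p: float | None
    aa_p: float | None
    func_dist: float | None
    defined: bool

    @classmethod
    def undefined(cls, haplotype_id: str) -> "HaplotypeDiversityRecord":
        return cls(haplotype_id, None, None, None, False)


def haplotype_diversity(
    haplotype_id: str,
    allele_ids: Iterable[str],
    nt_sequences: Mapping[str, str],
    model: GranthamModel | None = None,
    frame_offset: int = 0,
) -> HaplotypeDiversityRecord:
    """Mean pairwise diversity among the alleles of one haplotype.

    Single-allele haplotypes have no within-haplotype diversity and yield an
    undefined record (reported as NA downstream).
    """
    alleles = sorted(set(allele_ids))
    missing = [a for a in alleles if a not in nt_sequences]
    if missing:
        raise KeyError(f"no sequence for allele(s): {', '.join(missing)}")
    if len(alleles) < 2:
        return HaplotypeDiversityRecord.undefined(haplotype_id)
    nucl, aap, func = [], [], []
    for a1, a2 in itertools.combinations(alleles, 2):
        s1, s2 = nt_sequences[a1], nt_sequences[a2]
        nucl.append(p_distance(s1, s2, "nt"))
        t1, t2 = translate(s1, frame_offset), translate(s2, frame_offset)
        if len(t1) != len(t2):
            t1, t2 = align_pair(t1, t2, _protein_aligner())
        aap.append(p_distance(t1, t2, "aa"))
        func.append(functional_distance(t1, t2, model))
    return HaplotypeDiversityRecord(
        haplotype_id,
        float(np.mean(nucl)),
        float(np.mean(aap)),
        float(np.mean(func)),
        True,
    )


def _protein_aligner():
    return make_aligner()


METRICS = ("nucl_p", "aa_p", "func_dist")


def metric_correlation(
    records: Iterable[HaplotypeDiversityRecord],
) -> pd.DataFrame:
    """Pearson r and r^2 between each pair of the three diversity metrics,
    over records where all metrics are defined."""
    rows = [
        (r.nucl_p, r.aa_p, r.func_dist)
        for r in records
        if r.defined
    ]
    if len(rows) < 3:
        raise ValueError(f"need >=3 defined records, got {len(rows)}")
    data = np.asarray(rows, dtype=float)
    out = []
    for i, j in itertools.combinations(range(3), 2):
        x, y = data[:, i], data[:, j]
        if np.allclose(x, x[0]) or np.allclose(y, y[0]):
            raise ValueError(
                f"metric {METRICS[i]} or {METRICS[j]} is constant; "
                "correlation undefined"
            )
        r, p = stats.pearsonr(x, y)
        out.append((METRICS[i], METRICS[j], r, r * r, p))
    return pd.DataFrame(out, columns=["metric_1", "metric_2", "r", "r2", "p_value"])


def utr_pairwise_identity(sequences: Mapping[str, str]) -> pd.DataFrame:
    """Matrix of pairwise global-alignment identities between UTR sequences.

    Gap columns count as mismatches; identity 1.0 on the diagonal.
    """
    from .align import global_identity

    ids = list(sequences)
    if len(ids) < 2:
        raise ValueError("need at least two sequences")
    for sid in ids:
        if not sequences[sid]:
            raise ValueError(f"empty sequence: {sid}")
    mat = pd.DataFrame(np.eye(len(ids)), index=ids, columns=ids)
    for i1, i2 in itertools.combinations(ids, 2):
        ident = global_identity(sequences[i1], sequences[i2])
        mat.loc[i1, i2] = mat.loc[i2, i1] = ident
    return mat
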