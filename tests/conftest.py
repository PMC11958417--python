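import pandas as pd
import pytest

from mhc_hapseg.filtering import PRIMER_AB, PRIMER_C, ASVTable


def make_asv_table(columns: dict[str, dict[str, int]],
                   sequences: dict[str, str],
                   meta: dict[str, tuple[str, str, str]] | None = None) -> ASVTable:
    """Small ASV-table builder for tests.

    ``columns``: amplicon id -> {variant id: reads};
    ``meta``: amplicon id -> (sample, primer_set, replicate_tag); defaults to
    one A/B amplicon per sample named after the amplicon id.
    """
    variants = sorted({v for reads in columns.values() for v in reads})
    counts = pd.DataFrame(0, index=variants, columns=list(columns), dtype=int)
    for amp, reads in columns.items():
        for v, n in reads.items():
            counts.loc[v, amp] = n
    if meta is None:
        meta = {amp: (amp.split(".")[0], PRIMER_AB, "r1") for amp in columns}
    meta_df = pd.DataFrame(
        [(a, *meta[a]) for a in columns],
        columns=["amplicon_id", "sample_id", "primer_set", "replicate_tag"],
    ).set_index("amplicon_id")
    return ASVTable({v: sequences[v] for v in variants}, counts, meta_df)


@pytest.fixture
def ab_primer() -> str:
    return PRIMER_AB


@pytest.fixture
def c_primer() -> str:
    return PRIMER_C
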