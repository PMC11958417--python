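"""Filter-chain behaviour on constructed ASV tables: coverage floors,
off-target screening, per-amplicon frequency, artifact taxonomy, genotype
calling and replicate congruence."""

import numpy as np
import pytest

from mhc_hapseg.filtering import (
    ARTIFACT_1BP,
    ARTIFACT_CHIMERA,
    ARTIFACT_CROSS,
    LOW_FREQUENCY,
    PRIMER_AB,
    PRIMER_C,
    TRUE_ALLELE,
    FilterConfig,
    call_genotypes,
    classify_artifacts,
    filter_by_coverage,
    filter_low_frequency,
    filter_offtarget,
    replicate_congruence,
    run_filter_chain,
)
from mhc_hapseg.phasing import C_ABSENT_OBS, C_MISSING
from mhc_hapseg.simulate import (
    SimConfig,
    noise_free,
    simulate_asv_table,
    simulate_pedigree,
)

from conftest import make_asv_table

RNG = np.random.default_rng(1234)


def _seq(length=120):
    return "".join(RNG.choice(list("ACGT"), size=length))


A1, A2, A3 = _seq(), _seq(), _seq()


class TestCoverage:
    def test_amplicon_below_sample_floor_dropped(self):
        table = make_asv_table(
            {"s1.a": {"v1": 50, "v2": 49}, "s2.a": {"v1": 200, "v2": 30}},
            {"v1": A1, "v2": A2})
        out, status = filter_by_coverage(table, FilterConfig())
        assert list(out.counts.columns) == ["s2.a"]
        assert "s1.a" in status.dropped_amplicons

    def test_variant_below_max_coverage_dropped(self):
        table = make_asv_table(
            {"s1.a": {"v1": 200, "v2": 9}, "s2.a": {"v1": 150, "v2": 7},
             "s3.a": {"v1": 120, "v2": 3}},
            {"v1": A1, "v2": A2})
        out, status = filter_by_coverage(table, FilterConfig())
        assert list(out.counts.index) == ["v1"]
        assert status.state_of("v2", "s1.a") == "low_coverage"

    def test_clean_table_unchanged(self):
        table = make_asv_table(
            {"s1.a": {"v1": 90, "v2": 20}, "s2.a": {"v1": 150, "v2": 11}},
            {"v1": A1, "v2": A2})
        out, _ = filter_by_coverage(table, FilterConfig())
        assert out.counts.equals(table.counts)

    def test_empty_result_is_no_data_not_error(self):
        table = make_asv_table({"s1.a": {"v1": 10}}, {"v1": A1})
        out, _ = filter_by_coverage(table, FilterConfig())
        assert out.empty


class TestOfftarget:
    def test_reference_identical_retained(self):
        table = make_asv_table({"s1.a": {"v1": 500}}, {"v1": A1})
        out, _ = filter_offtarget(table, {"ref": A1}, FilterConfig())
        assert "v1" in out.variants

    def test_random_sequence_discarded(self):
        # an unrelated random sequence sits near 25 percent identity
        junk = _seq()
        table = make_asv_table({"s1.a": {"v1": 500, "v2": 400}},
                               {"v1": A1, "v2": junk})
        out, status = filter_offtarget(table, {"ref": A1}, FilterConfig())
        assert "v2" not in out.variants
        assert status.state_of("v2", "s1.a") == "offtarget"

    def test_95_percent_identity_retained(self):
        # equal length, 6 substitutions over 120 sites = 0.95 identity,
        # verified by direct column comparison (the alignment is gap-free)
        mutated = list(A1)
        for i in range(0, 12, 2):
            mutated[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[i]]
        mutated = "".join(mutated)
        assert sum(a == b for a, b in zip(A1, mutated)) / len(A1) == 0.95
        table = make_asv_table({"s1.a": {"v1": 500, "v2": 400}},
                               {"v1": A1, "v2": mutated})
        out, _ = filter_offtarget(table, {"ref": A1}, FilterConfig())
        assert "v2" in out.variants

    def test_empty_reference_set_rejected(self):
        table = make_asv_table({"s1.a": {"v1": 500}}, {"v1": A1})
        with pytest.raises(ValueError):
            filter_offtarget(table, {}, FilterConfig())


class TestLowFrequency:
    @pytest.mark.parametrize(
        "minor,expect_flagged",
        [(9, True),      # 9/1000 = 0.9% -> flagged
         (10, False),    # exactly 1.0% -> retained (strict less-than)
         ],
    )
    def test_per_amplicon_threshold(self, minor, expect_flagged):
        table = make_asv_table(
            {"s1.a": {"v1": 1000 - minor, "v2": minor}},
            {"v1": A1, "v2": A2})
        out, status = filter_low_frequency(table, FilterConfig())
        flagged = status.state_of("v2", "s1.a") == LOW_FREQUENCY
        assert flagged is expect_flagged
        assert ("v2" in out.variants) is not expect_flagged

    def test_single_variant_at_100_percent_retained(self):
        table = make_asv_table({"s1.a": {"v1": 500}}, {"v1": A1})
        out, _ = filter_low_frequency(table, FilterConfig())
        assert "v1" in out.variants

    def test_status_is_per_amplicon(self):
        table = make_asv_table(
            {"s1.a": {"v1": 1000, "v2": 5}, "s2.a": {"v1": 100, "v2": 900}},
            {"v1": A1, "v2": A2})
        out, status = filter_low_frequency(table, FilterConfig())
        assert status.state_of("v2", "s1.a") == LOW_FREQUENCY
        assert status.state_of("v2", "s2.a") is None
        assert "v2" in out.variants  # survives via s2.a


class TestArtifactClassification:
    def test_single_bp_mismatch_with_cooccurring_parent(self):
        child = A1[:-1] + ("A" if A1[-1] != "A" else "C")
        table = make_asv_table({"s1.a": {"v1": 3000, "v2": 100}},
                               {"v1": A1, "v2": child})
        status = classify_artifacts(table, FilterConfig())
        assert status.state_of("v2", "s1.a") == ARTIFACT_1BP
        assert status.state_of("v1", "s1.a") == TRUE_ALLELE

    def test_chimera_of_two_cooccurring_parents(self):
        chim = A1[:60] + A2[60:]
        table = make_asv_table(
            {"s1.a": {"v1": 2000, "v2": 1800, "v3": 90}},
            {"v1": A1, "v2": A2, "v3": chim})
        status = classify_artifacts(table, FilterConfig())
        assert status.state_of("v3", "s1.a") == ARTIFACT_CHIMERA

    def test_cross_amplicon_bleed_through(self):
        # v2 is a true allele at 40% in s2.a but a trace at 2% in s1.a
        table = make_asv_table(
            {"s1.a": {"v1": 980, "v2": 20}, "s2.a": {"v2": 400, "v3": 600}},
            {"v1": A1, "v2": A2, "v3": A3})
        status = classify_artifacts(table, FilterConfig())
        assert status.state_of("v2", "s1.a") == ARTIFACT_CROSS
        assert status.state_of("v2", "s2.a") == TRUE_ALLELE


class TestChainProperties:
    def _noisy_result(self, seed=0):
        cfg = SimConfig(seed=seed)
        truth = simulate_pedigree(cfg)
        table, _ = simulate_asv_table(truth, cfg)
        return truth, table

    def test_filter_chain_idempotent(self):
        _, table = self._noisy_result(2)
        first = run_filter_chain(table, None, FilterConfig())
        again = run_filter_chain(first.table, None, FilterConfig())
        assert set(again.table.variants) == set(first.table.variants)
        true_first = {
            k for k, (s, _) in first.status.records.items() if s == TRUE_ALLELE}
        true_again = {
            k for k, (s, _) in again.status.records.items() if s == TRUE_ALLELE}
        assert true_again == true_first

    def test_true_alleles_respect_thresholds(self):
        _, table = self._noisy_result(3)
        cfg = FilterConfig()
        result = run_filter_chain(table, None, cfg)
        freqs = result.table.frequencies()
        for (v, a), (state, _) in result.status.records.items():
            if state != TRUE_ALLELE:
                continue
            assert freqs.loc[v, a] >= cfg.min_frequency
            assert result.table.counts.loc[v].max() >= cfg.min_variant_max_coverage


class TestGenotypeCalling:
    def test_lineage_slots_and_c_statuses(self):
        c_seq = _seq()
        table = make_asv_table(
            {
                "s1.ab": {"a1": 600, "b1": 400},
                "s1.c": {"c1": 500},
                "s2.ab": {"a1": 900},
                "s3.ab": {"b1": 800},
                "s3.c": {"x": 100},
            },
            {"a1": A1, "b1": A2, "c1": c_seq, "x": A3},
            meta={
                "s1.ab": ("s1", PRIMER_AB, "r1"),
                "s1.c": ("s1", PRIMER_C, "r1"),
                "s2.ab": ("s2", PRIMER_AB, "r1"),
                "s3.ab": ("s3", PRIMER_AB, "r1"),
                "s3.c": ("s3", PRIMER_C, "r1"),
            })
        status = classify_artifacts(table, FilterConfig())
        lineage_of = {"a1": "A", "b1": "B", "c1": "C", "x": "offtarget"}
        geno = call_genotypes(table, status, lineage_of)
        assert geno["s1"].ab == {"a1", "b1"} and geno["s1"].c == {"c1"}
        assert geno["s2"].c_status == C_MISSING  # no C amplicon at all
        assert geno["s3"].c_status == C_ABSENT_OBS  # C amplicon, no C allele


class TestReplicates:
    def test_congruent_and_discordant_pairs(self):
        table = make_asv_table(
            {
                "s1.r1": {"v1": 600, "v2": 400},
                "s1.r2": {"v1": 500, "v2": 500},
                "s2.r1": {"v1": 900},
                "s2.r2": {"v1": 700, "v2": 300},
            },
            {"v1": A1, "v2": A2},
            meta={
                "s1.r1": ("s1", PRIMER_AB, "r1"),
                "s1.r2": ("s1", PRIMER_AB, "r2"),
                "s2.r1": ("s2", PRIMER_AB, "r1"),
                "s2.r2": ("s2", PRIMER_AB, "r2"),
            })
        status = classify_artifacts(table, FilterConfig())
        report = replicate_congruence(table, status)
        assert report.n_pairs == 2
        assert report.n_congruent == 1
        (a1, a2, diff), = report.discordances
        assert diff == ["v2"]

    def test_unmatched_replicate_pair_is_error(self):
        table = make_asv_table({"s1.r1": {"v1": 600}}, {"v1": A1})
        status = classify_artifacts(table, FilterConfig())
        with pytest.raises(KeyError):
            replicate_congruence(table, status, pairs=[("s1.r1", "nope")])

    def test_all_identical_pairs_100_percent(self):
        cfg = noise_free(SimConfig(seed=6, replicate_fraction=0.5))
        truth = simulate_pedigree(cfg)
        table, _ = simulate_asv_table(truth, cfg)
        result = run_filter_chain(table, dict(truth.alleles), None)
        report = replicate_congruence(result.table, result.status)
        assert report.n_pairs >= 20
        assert report.fraction_congruent == 1.0
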