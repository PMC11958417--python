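"""Segregation-based phasing: bipartition enumeration against brute-force
oracles, truth recovery on simulated families, recombinant parsimony,
hemizygosity, linkage expectations, catalog and architecture checks."""

import itertools

import numpy as np
import pytest

from mhc_hapseg.phasing import (
    C_ABSENT,
    C_ABSENT_OBS,
    C_MISSING,
    C_PRESENT,
    C_UNKNOWN,
    ArchitectureError,
    Haplotype,
    MHCGenotype,
    PedigreeFamily,
    apply_hemizygosity,
    architecture_checks,
    build_catalog,
    check_family_congruence,
    count_recombinants,
    enumerate_bipartitions,
    expected_diplotype_count,
    infer_hemizygosity,
    phase_family,
    union_explains,
)
from mhc_hapseg.simulate import (
    SimConfig,
    inject_recombinant,
    noise_free,
    simulate_pedigree,
)


def geno(ind, ab=(), c=(), c_status=None):
    c = tuple(c)
    if c_status is None:
        c_status = C_PRESENT if c else C_ABSENT_OBS
    return MHCGenotype(ind, frozenset(ab), frozenset(c), c_status)


def brute_force_bipartitions(ab, cs, c_status=C_PRESENT):
    """Independent enumeration: all unordered pairs of capacity-valid
    haplotypes whose union covers the parent's alleles exactly."""
    ab_subsets = [
        tuple(sorted(s))
        for n in range(3)
        for s in itertools.combinations(sorted(ab), n)
    ]
    c_opts = [None] + sorted(cs)
    haps = [(a, c) for a in ab_subsets for c in c_opts]
    key = lambda h: (h[0], h[1] or "")
    found = set()
    for h1, h2 in itertools.combinations_with_replacement(haps, 2):
        if set(h1[0]) | set(h2[0]) != set(ab):
            continue
        if {c for c in (h1[1], h2[1]) if c} != set(cs):
            continue
        found.add(tuple(sorted((h1, h2), key=key)))
    return found


class TestBipartitions:
    @pytest.mark.parametrize(
        "ab,cs",
        [(("a1", "b1", "b2"), ("c1",)),
         (("a1",), ()),
         (("b1", "b2"), ("c1", "c2")),
         ((), ("c1",)),
         (("a1", "a2", "b1", "b2"), ("c1", "c2"))],
    )
    def test_matches_brute_force_enumeration(self, ab, cs):
        parent = geno("p", ab, cs)
        got = {
            tuple(sorted(((h1.ab, h1.c), (h2.ab, h2.c)),
                         key=lambda h: (h[0], h[1] or "")))
            for h1, h2 in enumerate_bipartitions(parent)
        }
        assert got == brute_force_bipartitions(ab, cs)

    def test_single_allele_includes_homozygote_and_hemizygote(self):
        pairs = enumerate_bipartitions(geno("p", ("x",)))
        keys = {tuple(sorted((h1.key, h2.key))) for h1, h2 in pairs}
        assert ((("x",), ""), (("x",), "")) in keys  # homozygote
        assert (((), ""), (("x",), "")) in keys      # hemizygote-like

    def test_four_ab_and_two_c_gives_six_pairs(self):
        pairs = enumerate_bipartitions(
            geno("p", ("a1", "a2", "b1", "b2"), ("c1", "c2")))
        assert len(pairs) == 6

    def test_capacity_violation_is_architecture_error(self):
        with pytest.raises(ArchitectureError):
            enumerate_bipartitions(geno("p", tuple("abcde")))
        with pytest.raises(ValueError):
            geno("p", ("a",), ("c1", "c2", "c3"))
            enumerate_bipartitions(geno("p", ("a",), ("c1", "c2", "c3")))


def family_from_truth(mother_haps, father_haps, transmissions):
    """Build a family fixture: transmissions is a list of (mi, fi) index
    pairs into the parental haplotype pairs."""
    genotypes = {}

    def parent(ind, pair):
        ab = frozenset(pair[0].ab) | frozenset(pair[1].ab)
        c = frozenset(x for x in (pair[0].c, pair[1].c) if x)
        genotypes[ind] = MHCGenotype(
            ind, ab, c, C_PRESENT if c else C_ABSENT_OBS)

    parent("M", mother_haps)
    parent("F", father_haps)
    offspring = []
    for i, (mi, fi) in enumerate(transmissions):
        oid = f"o{i}"
        mh, fh = mother_haps[mi], father_haps[fi]
        ab = frozenset(mh.ab) | frozenset(fh.ab)
        c = frozenset(x for x in (mh.c, fh.c) if x)
        genotypes[oid] = MHCGenotype(
            oid, ab, c, C_PRESENT if c else C_ABSENT_OBS)
        offspring.append(oid)
    fam = PedigreeFamily(mother="M", offspring=offspring, fathers=["F"])
    return fam, genotypes


class TestPhaseFamily:
    MOTHER = (Haplotype(("a1", "b1")), Haplotype(("b2",), "c1"))
    FATHER = (Haplotype(("b3", "b4")), Haplotype(("a2",), "c2"))

    def test_recovers_constructed_truth(self):
        fam, genotypes = family_from_truth(
            self.MOTHER, self.FATHER,
            [(0, 0), (0, 1), (1, 0), (1, 1), (0, 0), (1, 1)])
        sol = phase_family(fam, genotypes)
        assert sol.multiplicity == 1
        assert {h.key for h in sol.parent_haplotypes["M"]} == {
            h.key for h in self.MOTHER}
        assert {h.key for h in sol.parent_haplotypes["F"]} == {
            h.key for h in self.FATHER}
        assert sol.unexplained == [] and sol.n_recombinants == 0

    def test_union_property_on_all_solutions(self):
        fam, genotypes = family_from_truth(
            self.MOTHER, self.FATHER, [(0, 0), (1, 1), (0, 1), (1, 0)])
        sol = phase_family(fam, genotypes)
        for alt in sol.alternatives:
            for oid, a in alt.assignments.items():
                mh = alt.parent_haplotypes["M"][a.maternal_index]
                ph = (alt.parent_haplotypes[a.paternal_parent][a.paternal_index]
                      if a.paternal_parent else a.external)
                assert union_explains(genotypes[oid], mh, ph)

    def test_underdetermined_family_reports_multiplicity(self):
        # one offspring carrying the mother's full allele set, father unknown
        genotypes = {
            "M": geno("M", ("a1", "b1", "b2")),
            "o1": geno("o1", ("a1", "b1", "b2")),
        }
        fam = PedigreeFamily("M", ["o1"], unknown_fathers=True)
        sol = phase_family(fam, genotypes)
        assert sol.multiplicity > 1

    def test_unknown_father_remainders_recover_truth(self):
        fam, genotypes = family_from_truth(
            self.MOTHER, self.FATHER,
            [(0, 0), (0, 1), (1, 0), (1, 1)])
        fam = PedigreeFamily("M", fam.offspring, fathers=[],
                             unknown_fathers=True)
        sol = phase_family(fam, genotypes)
        externals = {k for k in sol.external_haplotype_counts()}
        assert externals == {h.key for h in self.FATHER}

    def test_conflicting_alleles_raise_diagnostic(self):
        genotypes = {
            "M": geno("M", ("a1",)),
            "o1": geno("o1", ("z1", "z2", "z3", "z4")),
        }
        fam = PedigreeFamily("M", ["o1"], unknown_fathers=True)
        with pytest.raises(ValueError, match="z1"):
            phase_family(fam, genotypes)

    @pytest.mark.parametrize("seed", range(8))
    def test_simulated_families_recovered_when_identifiable(self, seed):
        cfg = noise_free(SimConfig(seed=seed, n_mothers=2, n_fathers=2,
                                   offspring_per_mother=8))
        truth = simulate_pedigree(cfg)
        for fam in truth.families:
            sol = phase_family(fam, truth.genotypes)
            assert sol.unexplained == []
            assert sol.n_recombinants == 0
            if sol.multiplicity == 1:
                for pid in [fam.mother] + fam.fathers:
                    assert {h.key for h in sol.parent_haplotypes[pid]} == {
                        h.key for h in truth.diplotypes[pid]}


class TestRecombinants:
    def test_constructed_recombinant_counted_once(self):
        # mother {a1,c1}/{a2,c2}; one offspring carries maternal a1 + c2
        mother = (Haplotype(("a1",), "c1"), Haplotype(("a2",), "c2"))
        father = (Haplotype(("b1",)), Haplotype(("b2",)))
        fam, genotypes = family_from_truth(
            mother, father, [(0, 0), (0, 1), (1, 0), (1, 1), (0, 0)])
        rec_oid = "oR"
        genotypes[rec_oid] = geno(rec_oid, ("a1", "b1"), ("c2",))
        fam.offspring.append(rec_oid)
        sol = phase_family(fam, genotypes)
        assert sol.n_recombinants == 1
        report = count_recombinants(sol, min_offspring=5)
        assert report.n_recombinant == 1
        assert "M" in report.eligible_parents

    def test_parsimony_against_brute_force(self):
        """The reported recombinant count is minimal: brute force over all
        bipartition combinations and per-offspring single-exchange options
        finds no solution with fewer recombinants."""
        mother = (Haplotype(("a1",), "c1"), Haplotype(("a2",), "c2"))
        father = (Haplotype(("b1",)), Haplotype(("b2",)))
        fam, genotypes = family_from_truth(
            mother, father, [(0, 0), (1, 1), (0, 1), (1, 0), (0, 0)])
        genotypes["oR"] = geno("oR", ("a1", "b2"), ("c2",))
        fam.offspring.append("oR")
        sol = phase_family(fam, genotypes)

        best = None
        m_parts = enumerate_bipartitions(genotypes["M"])
        f_parts = enumerate_bipartitions(genotypes["F"])
        for mp in m_parts:
            for fp in f_parts:
                n_expl = n_rec = 0
                for oid in fam.offspring:
                    off = genotypes[oid]
                    plain = any(
                        union_explains(off, mh, ph)
                        for mh in mp for ph in fp)
                    if plain:
                        n_expl += 1
                        continue
                    rec_m = [Haplotype(mp[0].ab, mp[1].c, mp[1].c_state),
                             Haplotype(mp[1].ab, mp[0].c, mp[0].c_state)]
                    rec_f = [Haplotype(fp[0].ab, fp[1].c, fp[1].c_state),
                             Haplotype(fp[1].ab, fp[0].c, fp[0].c_state)]
                    with_rec = any(
                        union_explains(off, mh, ph)
                        for mh in rec_m for ph in fp) or any(
                        union_explains(off, mh, ph)
                        for mh in mp for ph in rec_f)
                    if with_rec:
                        n_expl += 1
                        n_rec += 1
                score = (n_expl, -n_rec)
                if best is None or score > best:
                    best = score
        assert (len(sol.assignments), -sol.n_recombinants) == best

    def test_parent_with_fewer_than_five_offspring_excluded(self):
        mother = (Haplotype(("a1",), "c1"), Haplotype(("a2",), "c2"))
        father = (Haplotype(("b1",)), Haplotype(("b2",)))
        fam, genotypes = family_from_truth(
            mother, father, [(0, 0), (1, 1), (0, 1), (1, 0)])
        sol = phase_family(fam, genotypes)
        report = count_recombinants(sol, min_offspring=5)
        assert report.eligible_parents == []
        assert report.n_transmissions == 0

    def test_simulator_output_never_recombinant(self):
        cfg = noise_free(SimConfig(seed=12))
        truth = simulate_pedigree(cfg)
        sols = [phase_family(f, truth.genotypes) for f in truth.families]
        assert count_recombinants(sols).n_recombinant == 0

    def test_injected_recombinant_detected_exactly_once(self):
        cfg = noise_free(SimConfig(seed=13))
        truth = simulate_pedigree(cfg)
        oid = inject_recombinant(truth)
        assert oid is not None
        sols = [phase_family(f, truth.genotypes) for f in truth.families]
        assert sum(s.n_recombinants for s in sols) == 1


class TestHemizygosity:
    def test_absent_c_evidence_marks_haplotype(self):
        # father with a single C allele; an offspring lacking C under
        # successful amplification proves the no-C haplotype
        mother = (Haplotype(("a1", "b1")), Haplotype(("b2", "b3")))
        father = (Haplotype(("b4", "b5")), Haplotype(("b6",), "c1"))
        fam, genotypes = family_from_truth(
            mother, father, [(0, 0), (0, 1), (1, 0), (1, 1), (0, 0)])
        sol = phase_family(fam, genotypes)
        resolved = infer_hemizygosity(sol, genotypes)
        no_c_idx = [i for i, h in enumerate(sol.parent_haplotypes["F"])
                    if h.c is None]
        assert all(resolved[("F", i)] == C_ABSENT for i in no_c_idx)
        phased = apply_hemizygosity(sol, genotypes)
        assert any(h.c_state == C_ABSENT
                   for h in phased.parent_haplotypes["F"] if h.c is None)

    def test_missing_c_observations_are_not_evidence(self):
        mother = (Haplotype(("a1", "b1")), Haplotype(("b2", "b3")))
        father = (Haplotype(("b4", "b5")), Haplotype(("b6",), "c1"))
        fam, genotypes = family_from_truth(
            mother, father, [(0, 0), (1, 0), (0, 0)])
        for oid in fam.offspring:
            g = genotypes[oid]
            genotypes[oid] = MHCGenotype(oid, g.ab, frozenset(), C_MISSING)
        sol = phase_family(fam, genotypes)
        resolved = infer_hemizygosity(sol, genotypes)
        assert all(state == C_UNKNOWN for state in resolved.values())

    def test_two_distinct_c_alleles_no_hemizygosity(self):
        mother = (Haplotype(("a1",), "c1"), Haplotype(("b1",), "c2"))
        father = (Haplotype(("b2",)), Haplotype(("b3",)))
        fam, genotypes = family_from_truth(
            mother, father, [(0, 0), (1, 1), (0, 1), (1, 0)])
        sol = phase_family(fam, genotypes)
        assert all(h.c for h in sol.parent_haplotypes["M"])


class TestDiplotypeExpectation:
    def test_sixteen_vs_four(self):
        p1 = [("a", "b"), ("c", "d")]
        p2 = [("e", "f"), ("g", "h")]
        assert expected_diplotype_count(p1, p2, "independent") == 16
        assert expected_diplotype_count(p1, p2, "complete") == 4

    def test_single_locus_two_by_two(self):
        assert expected_diplotype_count(
            [("a", "b")], [("c", "d")], "independent") == 4

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n_loci = int(rng.integers(1, 4))
            def parent():
                return [tuple(rng.choice(list("abcd"), size=2))
                        for _ in range(n_loci)]
            p1, p2 = parent(), parent()
            got = expected_diplotype_count(p1, p2, "independent")
            g1 = set(itertools.product(*[set(l) for l in p1]))
            g2 = set(itertools.product(*[set(l) for l in p2]))
            oracle = len({tuple(sorted((a, b))) for a in g1 for b in g2})
            assert got == oracle


class TestCatalogAndArchitecture:
    def test_identical_haplotypes_merged_across_families(self):
        shared = (Haplotype(("a1", "b1")), Haplotype(("b2",), "c1"))
        father = (Haplotype(("b3", "b4")), Haplotype(("b5", "b6")))
        sols = []
        for tag in ("X", "Y"):
            fam, genotypes = family_from_truth(
                shared, father, [(0, 0), (0, 1), (1, 0), (1, 1), (0, 0)])
            fam.family_id = tag
            sols.append(phase_family(fam, genotypes))
        catalog = build_catalog(
            sols, {"a1": "A", "b1": "B", "b2": "B", "b3": "B", "b4": "B",
                   "b5": "B", "b6": "B", "c1": "C"}, min_offspring=5)
        assert len(catalog) == 4
        ab_entry = next(
            e for e in catalog.entries
            if e.haplotype.key == (("a1", "b1"), ""))
        assert {fam for fam, _ in ab_entry.sources} == {"X", "Y"}

    def test_architecture_violations_flagged(self):
        good = geno("ok", ("a1", "b1"), ("c1",))
        bad = MHCGenotype("bad", frozenset(), frozenset(("c1", "c2", "c3")),
                          C_PRESENT)
        report = architecture_checks(
            [good, bad],
            {"a1": "A", "b1": "B"})
        assert any("bad" in v for v in report.violations)

    def test_empty_genotype_set_empty_report(self):
        report = architecture_checks([], {})
        assert report.empty

    def test_simulated_population_respects_model(self):
        cfg = noise_free(SimConfig(seed=30, n_mothers=6, n_fathers=4,
                                   offspring_per_mother=10))
        truth = simulate_pedigree(cfg)
        report = architecture_checks(
            truth.genotypes.values(), truth.lineage_of)
        assert report.violations == []
        rho, _ = report.correlations[("A", "B")]
        assert rho < 0  # A and B share the capacity-4 region


class TestCongruence:
    def setup_method(self):
        self.mother = (Haplotype(("a1", "b1")), Haplotype(("b2",), "c1"))
        self.father = (Haplotype(("b3", "b4")), Haplotype(("b5",)))
        self.fam, self.genotypes = family_from_truth(
            self.mother, self.father, [(0, 0), (1, 1), (0, 1)])

    def test_clean_offspring_congruent(self):
        report = check_family_congruence([self.fam], self.genotypes)
        assert report.fraction_congruent == 1.0

    def test_foreign_allele_reported(self):
        self.genotypes["oX"] = geno("oX", ("a1", "zz"))
        self.fam.offspring.append("oX")
        report = check_family_congruence([self.fam], self.genotypes)
        rec = next(r for r in report.records if r.offspring == "oX")
        assert not rec.congruent and "zz" in rec.offending_alleles

    def test_alternative_father_suggested(self):
        alt_father = geno("F2", ("b7", "b8"))
        self.genotypes["F2"] = alt_father
        self.genotypes["oY"] = geno("oY", ("a1", "b1", "b7", "b8"))
        self.fam.offspring.append("oY")
        report = check_family_congruence(
            [self.fam], self.genotypes, candidate_fathers=["F", "F2"])
        rec = next(r for r in report.records if r.offspring == "oY")
        assert not rec.congruent and rec.alternative_fathers == ["F2"]
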