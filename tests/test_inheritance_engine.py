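"""Model matching, compound-het phasing, de novo, segregation, digenic."""

import itertools

import pytest

from conftest import BENIGN, DAMAGING, make_trio, make_variant, set_genotypes
from rpscreen.filter_cascade import FilterPolicy
from rpscreen.inheritance_engine import (
    build_units,
    check_segregation,
    detect_de_novo,
    flag_digenic,
    match_inheritance,
    scan_compound_het,
    scan_xlinked,
    unit_predictor_exclusion,
)
from rpscreen.io_formats import load_known_rp_panel
from rpscreen.models import (
    Affection,
    CandidateUnit,
    Consequence,
    DeNovoStatus,
    Family,
    Individual,
    InheritanceModel,
    Phase,
    Segregation,
    Sex,
    UnitModel,
    Zygosity,
)


@pytest.fixture(scope="module")
def panel():
    return load_known_rp_panel()


def singleton(model=InheritanceModel.SPORADIC, sex=Sex.FEMALE, fid="S1"):
    proband = Individual(f"{fid}_p", fid, sex=sex,
                         affected=Affection.AFFECTED)
    return Family(family_id=fid, members=[proband], declared_model=model)


class TestMatchInheritance:
    def test_dominant_gene_het_proband(self, panel):
        fam = make_trio(model=InheritanceModel.DOMINANT)
        v = make_variant(gene="RHO", hgvs="c.1040C>T")
        set_genotypes(fam, v, p=Zygosity.HET)
        assert match_inheritance(fam, "RHO", [v], panel) == \
            [UnitModel.DOMINANT]

    def test_recessive_gene_two_hets_suggest_comphet(self, panel):
        fam = make_trio(model=InheritanceModel.RECESSIVE)
        v1 = make_variant(gene="USH2A", hgvs="c.1A>G")
        v2 = make_variant(gene="USH2A", hgvs="c.2A>G")
        set_genotypes(fam, v1, p=Zygosity.HET)
        set_genotypes(fam, v2, p=Zygosity.HET)
        assert match_inheritance(fam, "USH2A", [v1, v2], panel) == \
            [UnitModel.RECESSIVE_COMPHET]

    def test_dual_mode_gene_homozygote_matches_recessive(self, panel):
        fam = singleton()
        v = make_variant(gene="RP1", hgvs="c.788_790delTAA",
                         consequence=Consequence.NONFRAMESHIFT_DELETION)
        set_genotypes(fam, v, p=Zygosity.HOM_ALT)
        assert match_inheritance(fam, "RP1", [v], panel) == \
            [UnitModel.RECESSIVE_HOM]

    def test_gene_absent_from_panel_yields_empty_list(self, panel):
        fam = singleton()
        v = make_variant(gene="NOTAGENE")
        set_genotypes(fam, v, p=Zygosity.HET)
        assert match_inheritance(fam, "NOTAGENE", [v], panel) == []

    def test_declared_dominant_family_not_scanned_for_recessive(self, panel):
        fam = make_trio(model=InheritanceModel.DOMINANT)
        v = make_variant(gene="USH2A", hgvs="c.1A>G")
        set_genotypes(fam, v, p=Zygosity.HOM_ALT)
        assert match_inheritance(fam, "USH2A", [v], panel) == []


class TestCompoundHet:
    def _family_with_pair(self, father_carries, mother_carries):
        """father/mother_carries from {'v1','v2','both','none'}."""
        fam = make_trio()
        v1 = make_variant(gene="USH2A", hgvs="c.1A>G")
        v2 = make_variant(gene="USH2A", hgvs="c.2A>G")

        def z(which, variant_name):
            return Zygosity.HET if which in (variant_name, "both") \
                else Zygosity.HOM_REF

        set_genotypes(fam, v1, p=Zygosity.HET,
                      f=z(father_carries, "v1"), m=z(mother_carries, "v1"))
        set_genotypes(fam, v2, p=Zygosity.HET,
                      f=z(father_carries, "v2"), m=z(mother_carries, "v2"))
        return fam, v1, v2

    @pytest.mark.parametrize(
        "father, mother",
        list(itertools.product(["v1", "v2", "none"], repeat=2)),
    )
    def test_exhaustive_parental_patterns(self, father, mother):
        """Over the 3x3 single-allele parental patterns: a unit exists for
        every pattern, trans-confirmed exactly when some unaffected parent
        carries exactly one allele of the pair."""
        fam, v1, v2 = self._family_with_pair(father, mother)
        units = scan_compound_het(fam, "USH2A", [v1, v2])
        assert len(units) == 1
        expected_trans = (father in ("v1", "v2")) or (mother in ("v1", "v2"))
        expected = Phase.TRANS_CONFIRMED if expected_trans \
            else Phase.PHASE_UNKNOWN
        assert units[0].phase is expected
        assert set(units[0].variants) == {v1.key, v2.key}

    @pytest.mark.parametrize("cis_parent", ["f", "m"])
    def test_pair_from_single_parent_rejected_as_cis(self, cis_parent):
        father = "both" if cis_parent == "f" else "none"
        mother = "both" if cis_parent == "m" else "none"
        fam, v1, v2 = self._family_with_pair(father, mother)
        assert scan_compound_het(fam, "USH2A", [v1, v2]) == []

    def test_singleton_sporadic_pair_is_phase_unknown(self):
        fam = singleton()
        v1 = make_variant(gene="USH2A", hgvs="c.1A>G")
        v2 = make_variant(gene="USH2A", hgvs="c.2A>G")
        set_genotypes(fam, v1, p=Zygosity.HET)
        set_genotypes(fam, v2, p=Zygosity.HET)
        (unit,) = scan_compound_het(fam, "USH2A", [v1, v2])
        assert unit.phase is Phase.PHASE_UNKNOWN
        assert unit.model is UnitModel.RECESSIVE_COMPHET

    def test_never_pairs_variant_with_itself_and_reports_once(self):
        fam = singleton()
        v1 = make_variant(gene="USH2A", hgvs="c.1A>G")
        set_genotypes(fam, v1, p=Zygosity.HET)
        assert scan_compound_het(fam, "USH2A", [v1, v1]) == []

    def test_three_hets_ranked_by_truncating_count(self):
        fam = singleton()
        missense1 = make_variant(gene="USH2A", hgvs="c.1A>G")
        missense2 = make_variant(gene="USH2A", hgvs="c.2A>G")
        stop = make_variant(gene="USH2A", hgvs="c.3A>T",
                            consequence=Consequence.STOPGAIN)
        for v in (missense1, missense2, stop):
            set_genotypes(fam, v, p=Zygosity.HET)
        units = scan_compound_het(fam, "USH2A", [missense1, missense2, stop])
        assert len(units) == 3
        assert stop.key in units[0].variants  # truncating pair ranked first

    def test_member_order_permutation_invariance(self):
        fam, v1, v2 = self._family_with_pair("v1", "v2")
        baseline = scan_compound_het(fam, "USH2A", [v1, v2])
        fam.members.reverse()
        permuted = scan_compound_het(fam, "USH2A", [v1, v2])
        assert [u.phase for u in baseline] == [u.phase for u in permuted]
        assert [u.variants for u in baseline] == \
            [u.variants for u in permuted]


class TestDeNovo:
    def test_both_parents_hom_ref_is_de_novo(self):
        fam = make_trio(model=InheritanceModel.SPORADIC)
        v = make_variant(gene="RP1", hgvs="c.5764A>G")
        set_genotypes(fam, v, p=Zygosity.HET, f=Zygosity.HOM_REF,
                      m=Zygosity.HOM_REF)
        assert detect_de_novo(fam, v) is DeNovoStatus.DE_NOVO

    def test_carrier_father_refutes(self):
        fam = make_trio()
        v = make_variant(gene="RP1", hgvs="c.1A>G")
        set_genotypes(fam, v, p=Zygosity.HET, f=Zygosity.HET)
        assert detect_de_novo(fam, v) is DeNovoStatus.INHERITED

    def test_unsequenced_mother_is_untestable(self):
        fam = make_trio()
        fam.member(f"{fam.family_id}_m").sequenced = False
        v = make_variant(gene="RP1", hgvs="c.1A>G")
        set_genotypes(fam, v, p=Zygosity.HET, f=Zygosity.HOM_REF)
        assert detect_de_novo(fam, v) is DeNovoStatus.UNTESTABLE

    def test_single_typed_carrier_parent_still_refutes(self):
        fam = make_trio()
        fam.member(f"{fam.family_id}_m").sequenced = False
        v = make_variant(gene="RP1", hgvs="c.1A>G")
        set_genotypes(fam, v, p=Zygosity.HET, f=Zygosity.HET)
        assert detect_de_novo(fam, v) is DeNovoStatus.INHERITED

    def test_zero_false_positives_on_noise_free_simulated_trios(self):
        """Direct-genotype oracle: a de novo call must match 'no parent
        carries the allele' exactly, across simulated cohorts."""
        from rpscreen.synthetic_cohort import SimulationConfig, \
            simulate_cohort
        families, variants, _ = simulate_cohort(SimulationConfig(
            seed=5, n_dominant=6, n_recessive=6, n_sporadic=12, n_xlinked=2,
            background_mean=30, causal_fraction_sporadic=1.0,
            sporadic_mix=(0.0, 0.0, 1.0)))
        checked = 0
        for fam in families:
            proband = fam.probands[0]
            father = fam.member(proband.father_id) if proband.father_id \
                else None
            mother = fam.member(proband.mother_id) if proband.mother_id \
                else None
            if father is None or mother is None:
                continue
            for v in variants[fam.family_id]:
                verdict = detect_de_novo(fam, v)
                oracle = (
                    fam.genotype(proband.sample_id, v.key).carries_alt
                    and not fam.genotype(father.sample_id, v.key).carries_alt
                    and not fam.genotype(mother.sample_id, v.key).carries_alt
                )
                if verdict is DeNovoStatus.DE_NOVO:
                    assert oracle
                    checked += 1
        assert checked > 0


class TestSegregation:
    def test_unaffected_sibling_with_dominant_allele_violates(self):
        fam = make_trio(model=InheritanceModel.DOMINANT,
                        father_affected=True)
        sib = Individual(f"{fam.family_id}_s", fam.family_id,
                         father_id=f"{fam.family_id}_f",
                         mother_id=f"{fam.family_id}_m",
                         sex=Sex.MALE, affected=Affection.UNAFFECTED)
        fam.members.append(sib)
        v = make_variant(gene="RHO", hgvs="c.1A>G")
        set_genotypes(fam, v, p=Zygosity.HET, f=Zygosity.HET,
                      s=Zygosity.HET)
        unit = CandidateUnit(fam.family_id, "RHO", UnitModel.DOMINANT,
                             (v.key,))
        assert check_segregation(fam, unit) is Segregation.VIOLATED

    def test_carrier_mother_of_half_a_comphet_is_consistent(self):
        fam = make_trio()
        v1 = make_variant(gene="USH2A", hgvs="c.1A>G")
        v2 = make_variant(gene="USH2A", hgvs="c.2A>G")
        set_genotypes(fam, v1, p=Zygosity.HET, m=Zygosity.HET)
        set_genotypes(fam, v2, p=Zygosity.HET, f=Zygosity.HET)
        unit = CandidateUnit(fam.family_id, "USH2A",
                             UnitModel.RECESSIVE_COMPHET,
                             (v1.key, v2.key))
        assert check_segregation(fam, unit) is Segregation.CONSISTENT

    def test_unaffected_relative_with_both_alleles_violates_comphet(self):
        fam = make_trio()
        sib = Individual(f"{fam.family_id}_s", fam.family_id,
                         father_id=f"{fam.family_id}_f",
                         mother_id=f"{fam.family_id}_m",
                         sex=Sex.FEMALE, affected=Affection.UNAFFECTED)
        fam.members.append(sib)
        v1 = make_variant(gene="USH2A", hgvs="c.1A>G")
        v2 = make_variant(gene="USH2A", hgvs="c.2A>G")
        set_genotypes(fam, v1, p=Zygosity.HET, f=Zygosity.HET,
                      s=Zygosity.HET)
        set_genotypes(fam, v2, p=Zygosity.HET, m=Zygosity.HET,
                      s=Zygosity.HET)
        unit = CandidateUnit(fam.family_id, "USH2A",
                             UnitModel.RECESSIVE_COMPHET,
                             (v1.key, v2.key))
        assert check_segregation(fam, unit) is Segregation.VIOLATED

    def test_no_sequenced_relatives_is_untested(self):
        fam = singleton()
        v = make_variant(gene="RHO", hgvs="c.1A>G")
        set_genotypes(fam, v, p=Zygosity.HET)
        unit = CandidateUnit(fam.family_id, "RHO", UnitModel.DOMINANT,
                             (v.key,))
        assert check_segregation(fam, unit) is Segregation.UNTESTED

    def test_unknown_affection_relative_cannot_violate(self):
        fam = make_trio()
        fam.member(f"{fam.family_id}_f").affected = Affection.UNKNOWN
        v = make_variant(gene="RHO", hgvs="c.1A>G")
        set_genotypes(fam, v, p=Zygosity.HET, f=Zygosity.HET)
        unit = CandidateUnit(fam.family_id, "RHO", UnitModel.DOMINANT,
                             (v.key,))
        # mother is typed hom_ref and unaffected: consistent, not violated
        assert check_segregation(fam, unit) is Segregation.CONSISTENT


class TestXlinked:
    def test_affected_hemizygous_male_yields_unit(self):
        fam = make_trio(model=InheritanceModel.XLINKED,
                        proband_sex=Sex.MALE)
        v = make_variant(gene="RPGR", hgvs="c.2236_2237delCT",
                         consequence=Consequence.FRAMESHIFT_DELETION)
        set_genotypes(fam, v, p=Zygosity.HEMIZYGOUS, m=Zygosity.HET)
        (unit,) = scan_xlinked(fam, "RPGR", [v])
        assert unit.model is UnitModel.XLINKED
        assert not unit.low_confidence

    def test_non_carrier_proband_yields_no_unit(self):
        fam = make_trio(model=InheritanceModel.XLINKED,
                        proband_sex=Sex.MALE)
        v = make_variant(gene="RPGR", hgvs="c.1A>G")
        set_genotypes(fam, v, p=Zygosity.HOM_REF, f=Zygosity.HEMIZYGOUS)
        assert scan_xlinked(fam, "RPGR", [v]) == []

    def test_affected_het_female_flagged_low_confidence(self):
        fam = make_trio(model=InheritanceModel.XLINKED,
                        proband_sex=Sex.FEMALE)
        v = make_variant(gene="RPGR", hgvs="c.1A>G")
        set_genotypes(fam, v, p=Zygosity.HET, m=Zygosity.HET)
        (unit,) = scan_xlinked(fam, "RPGR", [v])
        assert unit.low_confidence

    def test_affected_homozygous_female_full_confidence(self):
        fam = make_trio(model=InheritanceModel.XLINKED,
                        proband_sex=Sex.FEMALE)
        v = make_variant(gene="RPGR", hgvs="c.1A>G")
        set_genotypes(fam, v, p=Zygosity.HOM_ALT, m=Zygosity.HET,
                      f=Zygosity.HEMIZYGOUS)
        (unit,) = scan_xlinked(fam, "RPGR", [v])
        assert not unit.low_confidence


class TestUnitPredictorExclusion:
    def test_mixed_pair_kept(self):
        benign = make_variant(gene="RBP3", hgvs="c.3635C>T",
                              predictions=BENIGN)
        damaging = make_variant(gene="RBP3", hgvs="c.2603T>C",
                                predictions=DAMAGING)
        unit = CandidateUnit("F", "RBP3", UnitModel.RECESSIVE_COMPHET,
                             (benign.key, damaging.key))
        by_key = {benign.key: benign, damaging.key: damaging}
        assert not unit_predictor_exclusion(unit, by_key)

    def test_single_triple_benign_missense_excluded(self):
        v = make_variant(gene="RHO", hgvs="c.1A>G", predictions=BENIGN)
        unit = CandidateUnit("F", "RHO", UnitModel.DOMINANT, (v.key,))
        assert unit_predictor_exclusion(unit, {v.key: v})

    def test_double_benign_pair_excluded(self):
        v1 = make_variant(gene="RBP3", hgvs="c.1A>G", predictions=BENIGN)
        v2 = make_variant(gene="RBP3", hgvs="c.2A>G", predictions=BENIGN)
        unit = CandidateUnit("F", "RBP3", UnitModel.RECESSIVE_COMPHET,
                             (v1.key, v2.key))
        assert unit_predictor_exclusion(unit, {v1.key: v1, v2.key: v2})

    def test_truncating_unit_never_excluded(self):
        v = make_variant(gene="RP2", hgvs="c.445C>T",
                         consequence=Consequence.STOPGAIN,
                         predictions=__import__("rpscreen").models
                         .PredictionTriple())
        unit = CandidateUnit("F", "RP2", UnitModel.XLINKED, (v.key,))
        assert not unit_predictor_exclusion(unit, {v.key: v})


class TestDigenicAndBuild:
    def test_two_dominant_units_in_different_genes_flagged(self):
        fam = singleton(model=InheritanceModel.DOMINANT, fid="RP-62")
        u1 = CandidateUnit("RP-62", "RDH12", UnitModel.DOMINANT,
                           (("RDH12", "c.121G>T"),))
        u2 = CandidateUnit("RP-62", "SNRNP200", UnitModel.DOMINANT,
                           (("SNRNP200", "c.6025C>T"),))
        assert flag_digenic(fam, [u1, u2]) == [(u1, u2)]

    def test_single_unit_no_flag(self):
        fam = singleton()
        u1 = CandidateUnit("S1", "RDH12", UnitModel.DOMINANT,
                           (("RDH12", "c.1A>G"),))
        assert flag_digenic(fam, [u1]) == []

    def test_comphet_plus_dominant_not_digenic(self):
        fam = singleton()
        u1 = CandidateUnit("S1", "USH2A", UnitModel.RECESSIVE_COMPHET,
                           (("USH2A", "c.1A>G"), ("USH2A", "c.2A>G")))
        u2 = CandidateUnit("S1", "RDH12", UnitModel.DOMINANT,
                           (("RDH12", "c.3A>G"),))
        assert flag_digenic(fam, [u1, u2]) == []

    def test_emitted_units_reference_only_retained_variants(
            self, known_rp_rows, panel):
        from rpscreen.filter_cascade import apply_cascade
        from rpscreen.io_formats import families_from_table, \
            variants_by_family
        per_family = variants_by_family(known_rp_rows)
        for fam in families_from_table(known_rp_rows):
            retained, _ = apply_cascade(
                per_family[fam.family_id], fam.declared_model,
                FilterPolicy())
            retained_keys = {v.key for v in retained}
            for unit in build_units(fam, retained, panel, FilterPolicy()):
                assert set(unit.variants) <= retained_keys

    def test_violated_units_never_emitted(self):
        fam = make_trio(model=InheritanceModel.DOMINANT,
                        father_affected=True)
        sib = Individual(f"{fam.family_id}_s", fam.family_id,
                         father_id=f"{fam.family_id}_f",
                         mother_id=f"{fam.family_id}_m",
                         sex=Sex.MALE, affected=Affection.UNAFFECTED)
        fam.members.append(sib)
        v = make_variant(gene="RHO", hgvs="c.1A>G")
        set_genotypes(fam, v, p=Zygosity.HET, f=Zygosity.HET,
                      s=Zygosity.HET)
        panel = load_known_rp_panel()
        assert build_units(fam, [v], panel, FilterPolicy()) == []
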