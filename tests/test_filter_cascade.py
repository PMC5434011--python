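"""QC gate, model-dependent rarity filter, consequence and predictor rules."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import BENIGN, DAMAGING, make_variant
from rpscreen.filter_cascade import (
    FilterPolicy,
    IntervalSet,
    allele_frequency,
    apply_cascade,
    consequence_pass,
    frequency_pass,
    max_reference_maf,
    qc_pass,
    triple_benign,
)
from rpscreen.models import (
    Consequence,
    InheritanceModel,
    PolyphenCall,
    PredictionTriple,
    ProveanCall,
    SiftCall,
)


class TestAlleleFrequency:
    @pytest.mark.parametrize("ac, an, expected", [
        (4, 8640, 4 / 8640),        # ~4.63e-4
        (0, 8612, 0.0),
        (0, 0, 0.0),                # no observations != observed common
        (2, 4040, 2 / 4040),
    ])
    def test_values(self, ac, an, expected):
        assert allele_frequency(ac, an) == pytest.approx(expected)

    def test_count_exceeding_number_is_error(self):
        with pytest.raises(ValueError):
            allele_frequency(5, 4)


class TestQcPass:
    def test_boundary_quality_31_depth_5_passes(self):
        v = make_variant(quality=31, depth=5)
        assert qc_pass(v, FilterPolicy())

    def test_quality_exactly_30_fails_strict_gate(self):
        v = make_variant(quality=30, depth=100)
        assert not qc_pass(v, FilterPolicy())

    def test_depth_4_fails(self):
        v = make_variant(quality=60, depth=4)
        assert not qc_pass(v, FilterPolicy())

    def test_missing_qc_annotation_passes(self):
        assert qc_pass(make_variant(), FilterPolicy())

    def test_excluded_region_hit_fails(self, tmp_path):
        bed = tmp_path / "mhc.bed"
        bed.write_text("chr6\t100\t200\n")
        policy = FilterPolicy(excluded_regions=IntervalSet.from_bed(bed))
        inside = make_variant(chrom="chr6", pos=150, quality=60, depth=50)
        outside = make_variant(chrom="chr6", pos=250, quality=60, depth=50)
        assert not qc_pass(inside, policy)
        assert qc_pass(outside, policy)


class TestMaxReferenceMaf:
    def test_maximum_and_attaining_source(self):
        v = make_variant(frequencies={"exac": (4, 8640),
                                      "in_house": (2, 4040)})
        maf, source = max_reference_maf(v)
        assert maf == pytest.approx(2 / 4040)
        assert source == "in_house"

    def test_empty_frequency_map(self):
        assert max_reference_maf(make_variant()) == (0.0, None)

    def test_fixed_presence_source(self):
        v = make_variant(frequencies={"dbsnp_common": (1, 1)})
        assert max_reference_maf(v) == (1.0, "dbsnp_common")

    def test_absent_source_contributes_zero(self):
        v = make_variant(frequencies={"exac": (4, 8640)})
        maf, source = max_reference_maf(v, ["in_house"])
        assert (maf, source) == (0.0, None)


class TestFrequencyPass:
    policy = FilterPolicy()

    def test_recessive_below_half_percent_passes(self):
        v = make_variant(frequencies={"exac": (4, 1000)})  # 0.004
        assert frequency_pass(v, InheritanceModel.RECESSIVE, self.policy)

    def test_dominant_any_nonzero_frequency_excludes(self):
        v = make_variant(frequencies={"exac": (4, 8640)})
        assert not frequency_pass(v, InheritanceModel.DOMINANT, self.policy)

    def test_dominant_absent_from_references_passes(self):
        assert frequency_pass(make_variant(), InheritanceModel.DOMINANT,
                              self.policy)

    def test_xlinked_uses_recessive_threshold(self):
        v = make_variant(frequencies={"exac": (4, 1000)})
        assert frequency_pass(v, InheritanceModel.XLINKED, self.policy)
        v2 = make_variant(frequencies={"exac": (6, 1000)})
        assert not frequency_pass(v2, InheritanceModel.XLINKED, self.policy)


class TestConsequenceAndPredictor:
    @pytest.mark.parametrize("consequence, expected", [
        (Consequence.SYNONYMOUS, False),
        (Consequence.NONCODING, False),
        (Consequence.SPLICING, True),
        (Consequence.SPLICE_ACCEPTOR_REGION, True),
        (Consequence.NONFRAMESHIFT_DELETION, True),
        (Consequence.NONSYNONYMOUS, True),
        (Consequence.STOPGAIN, True),
    ])
    def test_consequence_rule(self, consequence, expected):
        assert consequence_pass(make_variant(consequence=consequence)) \
            is expected

    def test_triple_benign_requires_all_three(self):
        assert triple_benign(BENIGN)
        assert not triple_benign(PredictionTriple(
            ProveanCall.NEUTRAL, SiftCall.DAMAGING, PolyphenCall.BENIGN))
        assert not triple_benign(PredictionTriple())  # all missing

    def test_possibly_damaging_is_not_benign(self):
        p = PredictionTriple(ProveanCall.NEUTRAL, SiftCall.TOLERATED,
                             PolyphenCall.POSSIBLY_DAMAGING)
        assert not triple_benign(p)


def brute_force_retained(variants, model, policy,
                         defer_predictor_exclusion=True):
    """Independent per-rule oracle: tests every variant against every rule
    with no shared code path or short-circuiting."""
    kept = []
    for v in variants:
        ok = True
        if v.quality is not None and v.quality <= policy.min_quality:
            ok = False
        if v.depth is not None and v.depth < policy.min_depth:
            ok = False
        mafs = [ac / an if an > 0 else 0.0
                for ac, an in v.frequencies.values()]
        worst = max(mafs) if mafs else 0.0
        limit = policy.maf_dominant \
            if model is InheritanceModel.DOMINANT else policy.maf_recessive
        if worst > limit:
            ok = False
        if v.consequence in (Consequence.SYNONYMOUS, Consequence.NONCODING):
            ok = False
        if not defer_predictor_exclusion and \
                v.predictions.provean is ProveanCall.NEUTRAL and \
                v.predictions.sift is SiftCall.TOLERATED and \
                v.predictions.polyphen is PolyphenCall.BENIGN:
            ok = False
        if ok:
            kept.append(v)
    return kept


def random_cohort(rng, n):
    variants = []
    for i in range(n):
        variants.append(make_variant(
            gene=rng.choice(["RHO", "USH2A", "RP1", "EYS"]),
            hgvs=f"c.{i}A>G",
            consequence=rng.choice(list(Consequence)),
            predictions=rng.choice([DAMAGING, BENIGN, PredictionTriple()]),
            frequencies={
                "exac": (rng.choice([0, 0, 1, 5, 40, 400]), 8640),
                "in_house": (rng.choice([0, 0, 2, 30]), 4040),
            },
            quality=rng.choice([None, 10.0, 30.0, 31.0, 60.0]),
            depth=rng.choice([None, 3, 5, 50]),
        ))
    return variants


class TestApplyCascade:
    def test_all_58_fixture_rows_retained_under_family_models(
            self, known_rp_rows):
        from rpscreen.io_formats import variants_by_family
        from rpscreen.io_formats import families_from_table
        families = {f.family_id: f for f in
                    families_from_table(known_rp_rows)}
        per_family = variants_by_family(known_rp_rows)
        total = 0
        for fid, variants in per_family.items():
            retained, _ = apply_cascade(
                variants, families[fid].declared_model, FilterPolicy())
            total += len(retained)
        assert total == 58

    def test_trace_short_circuits_at_first_failure(self):
        v = make_variant(hgvs="c.9A>G",
                         consequence=Consequence.SYNONYMOUS,
                         frequencies={"exac": (400, 8640)})
        retained, trace = apply_cascade(
            [v], InheritanceModel.RECESSIVE, FilterPolicy())
        assert retained == []
        steps = [s for s, _, _ in trace.steps[v.key]]
        assert steps == ["qc", "frequency"]  # stops at the frequency failure
        assert trace.steps[v.key][-1][1] is False

    def test_empty_input(self):
        retained, trace = apply_cascade(
            [], InheritanceModel.DOMINANT, FilterPolicy())
        assert retained == [] and trace.steps == {}

    @pytest.mark.parametrize("model", [
        InheritanceModel.DOMINANT, InheritanceModel.RECESSIVE,
        InheritanceModel.SPORADIC,
    ])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle_on_random_cohorts(self, model, seed):
        rng = random.Random(seed)
        variants = random_cohort(rng, 200)
        for defer in (True, False):
            retained, _ = apply_cascade(
                variants, model, FilterPolicy(),
                defer_predictor_exclusion=defer)
            oracle = brute_force_retained(
                variants, model, FilterPolicy(),
                defer_predictor_exclusion=defer)
            assert [v.key for v in retained] == [v.key for v in oracle]

    def test_retained_set_is_order_invariant(self):
        rng = random.Random(7)
        variants = random_cohort(rng, 100)
        retained, _ = apply_cascade(
            variants, InheritanceModel.RECESSIVE, FilterPolicy())
        shuffled = variants[:]
        rng.shuffle(shuffled)
        retained2, _ = apply_cascade(
            shuffled, InheritanceModel.RECESSIVE, FilterPolicy())
        assert {v.key for v in retained} == {v.key for v in retained2}

    def test_dominant_retained_variants_absent_from_all_sources(self):
        rng = random.Random(13)
        variants = random_cohort(rng, 150)
        retained, _ = apply_cascade(
            variants, InheritanceModel.DOMINANT, FilterPolicy())
        for v in retained:
            assert all(ac == 0 for ac, _ in v.frequencies.values())

    @given(
        thresholds=st.tuples(
            st.floats(min_value=0.0, max_value=0.05),
            st.floats(min_value=0.0, max_value=0.05),
        ),
        seed=st.integers(min_value=0, max_value=2**16),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_raising_maf_threshold_never_shrinks_retained_set(
            self, thresholds, seed):
        low, high = sorted(thresholds)
        rng = random.Random(seed)
        variants = random_cohort(rng, 60)
        policy_low = FilterPolicy(maf_recessive=low,
                                  maf_rescue=min(low, 0.001))
        policy_high = FilterPolicy(maf_recessive=high,
                                   maf_rescue=min(high, 0.001))
        kept_low, _ = apply_cascade(
            variants, InheritanceModel.RECESSIVE, policy_low)
        kept_high, _ = apply_cascade(
            variants, InheritanceModel.RECESSIVE, policy_high)
        assert {v.key for v in kept_low} <= {v.key for v in kept_high}


class TestPolicy:
    def test_threshold_ordering_enforced(self):
        with pytest.raises(ValueError):
            FilterPolicy(maf_recessive=0.0005)  # below maf_rescue default

    def test_policy_from_yaml(self, tmp_path):
        f = tmp_path / "policy.yaml"
        f.write_text("min_quality: 20\nmaf_recessive: 0.01\n")
        policy = FilterPolicy.from_file(f)
        assert policy.min_quality == 20
        assert policy.maf_recessive == 0.01
        assert policy.maf_dominant == 0.0
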