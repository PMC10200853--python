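"""Filter chain: unions, each criterion at its printed boundary, germline
removal, the noise model, composition, and classification."""

import dataclasses

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mtsomatic.io_formats import (
    SOURCE_COHORT,
    SOURCE_PANEL,
    SOURCE_POPDB,
    GermlineResourceEntry,
    load_default_blacklist,
)
from mtsomatic.variant_filter import (
    LABEL_DYSPLASTIC,
    LABEL_SOMATIC,
    ClassifyConfig,
    FilterConfig,
    GermlineIndex,
    NoiseModel,
    Reason,
    apply_noise_filter,
    check_position_blacklist,
    check_read_evidence,
    classify_somatic_status,
    estimate_noise,
    filter_variant,
    remove_germline,
    union_calls,
)

from conftest import make_call

CFG = FilterConfig()
BLACKLIST = load_default_blacklist()


class TestUnion:
    def calls(self, positions, caller="caller_a"):
        return [make_call(position=p, callers=frozenset({caller})) for p in positions]

    def test_disjoint_union(self):
        union = union_calls(self.calls([1, 2]), self.calls([3, 4, 5], "caller_b"))
        assert len(union) == 5

    def test_identical_sets_idempotent(self):
        a = self.calls([1, 2, 3, 4])
        b = self.calls([1, 2, 3, 4], "caller_b")
        union = union_calls(a, b)
        assert len(union) == 4
        assert all(c.callers == {"caller_a", "caller_b"} for c in union)

    def test_inclusion_exclusion_single_overlap(self):
        union = union_calls(self.calls([1, 2, 3]), self.calls([3, 4, 5], "caller_b"))
        assert len(union) == 5

    def test_commutative_on_keys_and_callers(self):
        a = self.calls([10, 20, 30])
        b = self.calls([20, 40], "caller_b")
        ab = union_calls(a, b)
        ba = union_calls(b, a)
        assert [c.key for c in ab] == [c.key for c in ba]
        assert [c.callers for c in ab] == [c.callers for c in ba]

    def test_overlap_keeps_first_annotations_with_provenance(self):
        a = [make_call(position=5, variant_base_quality=30.0)]
        b = [make_call(position=5, variant_base_quality=38.0,
                       callers=frozenset({"caller_b"}))]
        merged = union_calls(a, b)[0]
        assert merged.variant_base_quality == 30.0
        (secondary,) = merged.provenance["secondary"].values()
        assert secondary["variant_base_quality"] == 38.0

    def test_indel_status_derived_from_alleles(self):
        # is_indel is derived from the (ref, alt) key itself, so two records
        # sharing a key can never disagree about it
        assert make_call(ref_allele="A", alt_allele="AT").is_indel
        assert not make_call(ref_allele="A", alt_allele="G").is_indel
        merged = union_calls([make_call(ref_allele="A", alt_allele="AT")],
                             [make_call(ref_allele="A", alt_allele="AT",
                                        callers=frozenset({"caller_b"}))])
        assert len(merged) == 1 and merged[0].is_indel

    def test_cross_sample_union_rejected(self):
        with pytest.raises(ValueError, match="sample"):
            union_calls([make_call(sample_id="s1")], [make_call(sample_id="s2")])


class TestBlacklist:
    @pytest.mark.parametrize("position,expected", [
        (302, Reason.BLACKLIST), (315, Reason.BLACKLIST),  # first region, inclusive
        (301, None), (316, None),
        (513, Reason.BLACKLIST), (525, Reason.BLACKLIST),
        (568, Reason.BLACKLIST), (573, Reason.BLACKLIST),
        (956, Reason.BLACKLIST), (965, Reason.BLACKLIST),
        (3105, Reason.BLACKLIST), (3109, Reason.BLACKLIST),
        (5895, Reason.BLACKLIST), (5899, Reason.BLACKLIST),
        (8270, Reason.BLACKLIST), (8289, Reason.BLACKLIST),
        (8269, None), (8290, None),
    ])
    def test_snv_boundaries(self, position, expected):
        call = make_call(position=position)
        assert check_position_blacklist(call, BLACKLIST) == expected

    def test_indel_only_region(self):
        snv = make_call(position=16185)
        indel = make_call(position=16185, ref_allele="A", alt_allele="AT")
        assert check_position_blacklist(snv, BLACKLIST) is None
        assert check_position_blacklist(indel, BLACKLIST) == Reason.BLACKLIST
        assert check_position_blacklist(
            make_call(position=16180, ref_allele="A", alt_allele="AT"),
            BLACKLIST) == Reason.BLACKLIST
        assert check_position_blacklist(
            make_call(position=16196, ref_allele="A", alt_allele="AT"),
            BLACKLIST) is None


# Each entry: (criterion, kwargs that PASS at the boundary, kwargs that FAIL
# one grid step across it). Thresholds as printed in the filter recipe.
BOUNDARY_CASES = [
    (Reason.SUPPORT,
     dict(variant_reads=10, forward_variant_reads=5),
     dict(variant_reads=9, forward_variant_reads=5)),
    (Reason.BASE_QUALITY,
     dict(variant_base_quality=20.0), dict(variant_base_quality=19.9)),
    (Reason.STRAND,  # strict open interval (0.1, 0.9)
     dict(variant_reads=100, forward_variant_reads=11, total_depth=1000),
     dict(variant_reads=100, forward_variant_reads=90, total_depth=1000)),
    (Reason.STRAND,
     dict(variant_reads=100, forward_variant_reads=89, total_depth=1000),
     dict(variant_reads=100, forward_variant_reads=10, total_depth=1000)),
    (Reason.READ_POSITION,  # strict open interval (0.15, 0.85)
     dict(mean_read_position=0.151), dict(mean_read_position=0.15)),
    (Reason.READ_POSITION,
     dict(mean_read_position=0.849), dict(mean_read_position=0.85)),
    (Reason.LENGTH_DIFF,  # ref - var < 25
     dict(ref_read_length=150.0, var_read_length=126.0),
     dict(ref_read_length=150.0, var_read_length=125.0)),
    (Reason.MAPQ_DIFF,  # ref - var < 10
     dict(ref_mapq=60.0, var_mapq=51.0),
     dict(ref_mapq=60.0, var_mapq=50.0)),
    (Reason.NORMAL_CONTEXT,  # strictly > 0.80
     dict(normal_context_fraction=0.801),
     dict(normal_context_fraction=0.80)),
    (Reason.NM_DIFF,  # var - ref <= 3
     dict(ref_nm=1.0, var_nm=4.0),
     dict(ref_nm=1.0, var_nm=4.1)),
]


class TestReadEvidence:
    def test_baseline_passes(self, baseline_call):
        assert check_read_evidence(baseline_call, CFG) == []

    @pytest.mark.parametrize("reason,passing,failing", BOUNDARY_CASES,
                             ids=lambda v: str(v) if isinstance(v, Reason) else "")
    def test_each_criterion_is_a_sharp_boundary(self, reason, passing, failing):
        assert check_read_evidence(make_call(**passing), CFG) == []
        assert check_read_evidence(make_call(**failing), CFG) == [reason]

    def test_violations_reported_independently(self):
        call = make_call(variant_reads=9, forward_variant_reads=9,
                         variant_base_quality=10.0)
        reasons = check_read_evidence(call, CFG)
        assert Reason.SUPPORT in reasons
        assert Reason.BASE_QUALITY in reasons
        assert Reason.STRAND in reasons

    def test_zero_variant_reads_skips_ratio(self):
        call = make_call(variant_reads=0, forward_variant_reads=0)
        reasons = check_read_evidence(call, CFG)
        assert reasons == [Reason.SUPPORT]

    def test_adjacent_to_germline_waives_normal_context_only(self):
        call = make_call(normal_context_fraction=0.5, adjacent_to_germline=True)
        assert check_read_evidence(call, CFG) == []
        call = make_call(normal_context_fraction=0.5, adjacent_to_germline=True,
                         variant_base_quality=10.0)
        assert check_read_evidence(call, CFG) == [Reason.BASE_QUALITY]

    def test_missing_annotation_fails_closed(self):
        call = make_call(variant_base_quality=None)
        assert check_read_evidence(call, CFG) == [Reason.MISSING_ANNOTATION]


class TestGermline:
    def entry(self, source, freq, position=1000, allele="G"):
        return GermlineResourceEntry(position, allele, source, freq)

    @pytest.mark.parametrize("source,freq,expected", [
        (SOURCE_POPDB, 0.02, True),    # dbSNP-style: freq > 1%
        (SOURCE_POPDB, 0.01, False),   # exactly 1% is not > 1%
        (SOURCE_COHORT, 0.96, True),   # panel VAF > 95%
        (SOURCE_COHORT, 0.95, False),
        (SOURCE_PANEL, 0.96, True),
        (SOURCE_PANEL, 0.50, False),
    ])
    def test_resource_thresholds(self, source, freq, expected):
        index = GermlineIndex([self.entry(source, freq)], [], CFG)
        verdict = remove_germline([make_call()], [self.entry(source, freq)], [], CFG)[0]
        assert index.is_germline(1000, "G") is expected
        assert (Reason.GERMLINE in verdict.failed_reasons) is expected

    def test_paired_normal_vaf(self):
        normal_hi = make_call(sample_id="n", variant_reads=960, total_depth=1000,
                              forward_variant_reads=480)
        normal_lo = make_call(sample_id="n", variant_reads=950, total_depth=1000,
                              forward_variant_reads=475)
        assert remove_germline([make_call()], [], [normal_hi], CFG)[0].failed_reasons \
            == [Reason.GERMLINE]
        assert remove_germline([make_call()], [], [normal_lo], CFG)[0].passed

    def test_absent_everywhere_passes(self):
        assert remove_germline([make_call()], [], [], CFG)[0].passed

    def test_adjacency_window(self):
        resource = [self.entry(SOURCE_COHORT, 0.99, position=1002, allele="T")]
        index = GermlineIndex(resource, [], CFG)
        assert index.is_adjacent(make_call(position=1000))
        assert not index.is_adjacent(make_call(position=997))


class TestNoise:
    def panel(self, vaf_by_sample, position=500):
        calls = {}
        for sample, vaf in vaf_by_sample.items():
            if vaf is None:
                calls[sample] = []
            else:
                vr = int(round(vaf * 10000))
                calls[sample] = [make_call(sample_id=sample, position=position,
                                           total_depth=10000, variant_reads=vr,
                                           forward_variant_reads=vr // 2)]
        return calls

    def test_no_signal_means_floor(self):
        model = estimate_noise(self.panel({"a": None, "b": None}), floor=0.005)
        assert model.level(500) == 0.005

    def test_mean_plus_three_sd_equal_vafs(self):
        model = estimate_noise(self.panel({"a": 0.01, "b": 0.01, "c": 0.01}),
                               floor=0.005)
        assert model.level(500) == pytest.approx(0.01)

    def test_single_normal_sd_zero(self):
        model = estimate_noise(self.panel({"a": 0.04}), floor=0.005)
        assert model.level(500) == pytest.approx(0.04)

    def test_absent_samples_contribute_zero(self):
        # vafs {0.03, 0, 0}: mean 0.01, sd 0.017320..., mean+3sd = 0.061961...
        model = estimate_noise(self.panel({"a": 0.03, "b": None, "c": None}),
                               floor=0.005)
        expected = 0.01 + 3 * (0.0003 ** 0.5)
        assert model.level(500) == pytest.approx(expected, rel=1e-6)

    def test_empty_panel_instructs_floor_model(self):
        with pytest.raises(ValueError, match="floor"):
            estimate_noise({})

    @pytest.mark.parametrize("vaf,noise,expected", [
        (0.30, 0.005, None),
        (0.004, 0.005, Reason.BELOW_NOISE),
        (0.005, 0.005, None),  # "lower than" is strict: equality passes
    ])
    def test_noise_filter_strict(self, vaf, noise, expected):
        model = NoiseModel({1000: noise}, floor=min(noise, 0.005))
        vr = int(round(vaf * 100000))
        call = make_call(total_depth=100000, variant_reads=vr,
                         forward_variant_reads=vr // 2)
        assert apply_noise_filter(call, model) == expected


class TestComposition:
    def test_multiple_stage_reasons_accumulate(self):
        call = make_call(position=302, variant_reads=9, forward_variant_reads=5)
        verdict = filter_variant(call, CFG, BLACKLIST)
        assert verdict.failed_reasons == [Reason.BLACKLIST, Reason.SUPPORT]

    def test_fully_passing(self, baseline_call):
        verdict = filter_variant(baseline_call, CFG, BLACKLIST,
                                 GermlineIndex([], [], CFG),
                                 NoiseModel({}, 0.005))
        assert verdict.passed and verdict.failed_reasons == []

    def test_support_and_strand_both_reported(self):
        call = make_call(variant_reads=9, forward_variant_reads=9)
        verdict = filter_variant(call, CFG, BLACKLIST)
        assert set(verdict.failed_reasons) == {Reason.SUPPORT, Reason.STRAND}

    def test_filtering_is_idempotent(self, small_cohort):
        from mtsomatic.io_formats import CALLER_A, CALLER_B

        resource = small_cohort.germline_resource
        normals = {s: small_cohort.calls[CALLER_A].get(s, [])
                   for s in small_cohort.ground_truth.samples
                   if s.endswith("-N")}
        model = estimate_noise(normals)
        for sample in [s for s in small_cohort.ground_truth.samples if s.endswith("-T")]:
            union = union_calls(small_cohort.calls[CALLER_A].get(sample, []),
                                small_cohort.calls[CALLER_B].get(sample, []))
            index = GermlineIndex(resource, normals.get(sample[:-2] + "-N", []), CFG)
            passing = [v.call for v in
                       (filter_variant(c, CFG, BLACKLIST, index, model) for c in union)
                       if v.passed]
            again = [v.call for v in
                     (filter_variant(c, CFG, BLACKLIST, index, model) for c in passing)
                     if v.passed]
            assert [c.key for c in again] == [c.key for c in passing]

    @pytest.mark.parametrize("reason,passing,failing", BOUNDARY_CASES,
                             ids=lambda v: str(v) if isinstance(v, Reason) else "")
    def test_boundary_flip_changes_exactly_one_reason(self, reason, passing, failing):
        """Crossing one printed threshold flips that reason code and no other."""
        index = GermlineIndex([], [], CFG)
        model = NoiseModel({}, 0.005)
        before = filter_variant(make_call(**passing), CFG, BLACKLIST, index, model)
        after = filter_variant(make_call(**failing), CFG, BLACKLIST, index, model)
        assert before.failed_reasons == []
        assert after.failed_reasons == [reason]


class TestClassification:
    def test_zero_normal_signal_is_somatic(self, baseline_call):
        result = classify_somatic_status(baseline_call, 0.0)
        assert result.label == LABEL_SOMATIC
        assert result.tumour_vaf == pytest.approx(0.3)

    def test_low_normal_expanded_in_tumour_is_dysplastic(self):
        call = make_call(variant_reads=400, forward_variant_reads=200)  # VAF 0.40
        result = classify_somatic_status(call, 0.05)
        assert result.label == LABEL_DYSPLASTIC

    def test_insufficient_expansion_dropped(self):
        call = make_call(variant_reads=60, forward_variant_reads=30,
                         total_depth=1000)  # VAF 0.06 vs normal 0.05
        assert classify_somatic_status(call, 0.05) is None

    def test_near_fixed_in_normal_dropped(self, baseline_call):
        assert classify_somatic_status(baseline_call, 0.97) is None

    def test_normal_vaf_domain_checked(self, baseline_call):
        with pytest.raises(ValueError, match="VAF"):
            classify_somatic_status(baseline_call, 1.2)

    def test_failed_verdict_rejected(self, baseline_call):
        from mtsomatic.variant_filter import Verdict

        verdict = Verdict(baseline_call, [Reason.SUPPORT])
        with pytest.raises(ValueError, match="passing"):
            classify_somatic_status(baseline_call, 0.0, verdict=verdict)

    def test_thresholds_configurable(self):
        call = make_call(variant_reads=400, forward_variant_reads=200)
        cfg = ClassifyConfig(somatic_max_normal_vaf=0.10)
        assert classify_somatic_status(call, 0.05, cfg).label == LABEL_SOMATIC


@given(
    variant_reads=st.integers(0, 1000),
    forward_fraction=st.floats(0.0, 1.0),
    vbq=st.floats(0.0, 45.0),
    mrp=st.floats(0.0, 1.0),
    len_diff=st.floats(-50.0, 50.0),
    mapq_diff=st.floats(-30.0, 30.0),
    ncf=st.floats(0.0, 1.0),
    nm_diff=st.floats(-5.0, 10.0),
)
@settings(max_examples=300, deadline=None)
def test_verdict_passed_iff_no_reasons(variant_reads, forward_fraction, vbq, mrp,
                                       len_diff, mapq_diff, ncf, nm_diff):
    """passed <=> failed_reasons empty, for arbitrary evidence values."""
    call = make_call(
        total_depth=max(variant_reads, 1000),
        variant_reads=variant_reads,
        forward_variant_reads=int(forward_fraction * variant_reads),
        variant_base_quality=vbq,
        mean_read_position=mrp,
        ref_read_length=150.0,
        var_read_length=150.0 - len_diff,
        ref_mapq=60.0,
        var_mapq=60.0 - mapq_diff,
        normal_context_fraction=ncf,
        ref_nm=2.0,
        var_nm=2.0 + nm_diff,
    )
    verdict = filter_variant(call, CFG, BLACKLIST, GermlineIndex([], [], CFG),
                             NoiseModel({}, 0.005))
    assert verdict.passed == (not verdict.failed_reasons)
    reasons = check_read_evidence(call, CFG)
    assert (variant_reads < 10) == (Reason.SUPPORT in reasons)
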