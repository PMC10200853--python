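"""Cohort generator: determinism, ground-truth bookkeeping, round trips."""

import dataclasses
import json

import pytest

from mtsomatic.io_formats import CALLER_A, CALLER_B, MT_LENGTH, read_variant_vcf
from mtsomatic.synthetic_data import (
    ARTIFACT_PREFIX,
    LABEL_GERMLINE,
    LABEL_TRUE_SOMATIC,
    SimulationSpec,
    load_ground_truth,
    simulate_cohort,
    write_fixture_bundle,
)
from mtsomatic.variant_filter import MtVariantCall


def tiny_spec(**kwargs):
    defaults = dict(n_true_somatic_per_tumour=2, n_germline_haplogroup=5,
                    n_population_polymorphisms=2, n_noise_positions=3, seed=11)
    defaults.update(kwargs)
    return SimulationSpec.single_group(n=2, **defaults)


class TestDeterminism:
    def test_same_seed_same_cohort(self):
        a = simulate_cohort(tiny_spec())
        b = simulate_cohort(tiny_spec())
        assert a.reference == b.reference
        assert a.depth_rows == b.depth_rows
        assert dataclasses.asdict(a.ground_truth.variants[0]) == \
            dataclasses.asdict(b.ground_truth.variants[0])
        for caller in (CALLER_A, CALLER_B):
            assert set(a.calls[caller]) == set(b.calls[caller])
            for sample in a.calls[caller]:
                assert [c.key for c in a.calls[caller][sample]] == \
                    [c.key for c in b.calls[caller][sample]]

    def test_same_seed_byte_identical_bundles(self, tmp_path):
        d1, d2 = tmp_path / "one", tmp_path / "two"
        write_fixture_bundle(simulate_cohort(tiny_spec()), d1)
        write_fixture_bundle(simulate_cohort(tiny_spec()), d2)
        for path in sorted(d1.rglob("*")):
            if path.is_file():
                other = d2 / path.relative_to(d1)
                assert path.read_bytes() == other.read_bytes(), path.name

    def test_different_seed_differs(self):
        a = simulate_cohort(tiny_spec(seed=1))
        b = simulate_cohort(tiny_spec(seed=2))
        assert a.reference != b.reference

    def test_earlier_samples_stable_under_extension(self):
        small = simulate_cohort(tiny_spec())
        big = simulate_cohort(SimulationSpec.single_group(
            n=4, n_true_somatic_per_tumour=2, n_germline_haplogroup=5,
            n_population_polymorphisms=2, n_noise_positions=3, seed=11))
        for sample in ("P01-T", "P02-T"):
            assert [c.key for c in small.calls[CALLER_A][sample]] == \
                [c.key for c in big.calls[CALLER_A][sample]]


class TestGroundTruth:
    def test_label_conservation(self):
        cohort = simulate_cohort(tiny_spec())
        emitted = set()
        for caller in (CALLER_A, CALLER_B):
            for sample, calls in cohort.calls[caller].items():
                emitted.update((sample,) + c.key for c in calls)
        truth = {(v.sample_id, v.position, v.ref_allele, v.alt_allele)
                 for v in cohort.ground_truth.variants}
        assert emitted == truth
        assert len(truth) == len(cohort.ground_truth.variants)

    def test_fixed_somatic_count(self):
        cohort = simulate_cohort(tiny_spec())
        somatic = cohort.ground_truth.by_label(LABEL_TRUE_SOMATIC)
        assert len(somatic) == 2 * 2  # 2 per tumour, 2 tumours
        assert all(v.sample_id.endswith("-T") for v in somatic)

    def test_germline_shared_between_tumour_and_normal(self):
        cohort = simulate_cohort(tiny_spec())
        germline = cohort.ground_truth.by_label(LABEL_GERMLINE)
        tumour_keys = {(v.position, v.alt_allele) for v in germline
                       if v.sample_id == "P01-T"}
        normal_keys = {(v.position, v.alt_allele) for v in germline
                       if v.sample_id == "P01-N"}
        assert tumour_keys == normal_keys
        assert len(tumour_keys) >= 5

    def test_quiet_spec_emits_no_tumour_specific_variants(self):
        spec = tiny_spec(n_true_somatic_per_tumour=0,
                         artifact_rates={}, n_noise_positions=0)
        cohort = simulate_cohort(spec)
        labels = {v.label for v in cohort.ground_truth.variants
                  if v.sample_id.endswith("-T")}
        assert labels <= {LABEL_GERMLINE}

    def test_artifacts_only_in_tumours(self):
        cohort = simulate_cohort(tiny_spec(seed=3))
        artifacts = cohort.ground_truth.by_label(ARTIFACT_PREFIX)
        assert all(v.sample_id.endswith("-T") for v in artifacts)

    def test_depth_inversion_matches_estimator(self):
        """Expected chrM depth is constructed so the estimator is unbiased."""
        cohort = simulate_cohort(tiny_spec())
        spec = cohort.spec
        for sample, info in cohort.ground_truth.samples.items():
            corr = info["f"] * info["ploidy"] + (1 - info["f"]) * 2
            expected_mu = spec.mean_depth_auto * info["true_mtCN"] / corr
            row = next(d for d in cohort.depth_rows if d.sample_id == sample)
            assert row.mean_dp_chrm == pytest.approx(expected_mu, rel=0.25)


class TestBundle:
    def test_manifest_and_round_trip(self, small_cohort, small_bundle):
        directory, manifest = small_bundle
        assert manifest["seed"] == small_cohort.spec.seed
        assert (directory / "manifest.json").exists()
        listed = json.loads((directory / "manifest.json").read_text())["files"]
        for name in listed:
            assert (directory / name).exists(), name
        # VCF round trip reproduces the generated records
        sample = "P01-T"
        raw = read_variant_vcf(directory / "vcf" / f"{sample}.{CALLER_A}.vcf",
                               CALLER_A)
        back = [MtVariantCall.from_raw(r, sample) for r in raw]
        orig = small_cohort.calls[CALLER_A][sample]
        assert [c.key for c in back] == [c.key for c in orig]
        for o, b in zip(orig, back):
            assert b.vaf == pytest.approx(o.vaf, abs=1e-6)
            assert b.variant_base_quality == pytest.approx(o.variant_base_quality,
                                                           rel=1e-5)

    def test_ground_truth_loadable(self, small_cohort, small_bundle):
        directory, _ = small_bundle
        truth = load_ground_truth(directory / "ground_truth.json")
        assert len(truth.variants) == len(small_cohort.ground_truth.variants)
        assert truth.samples.keys() == small_cohort.ground_truth.samples.keys()

    def test_reference_is_fasta_of_full_length(self, small_bundle):
        directory, _ = small_bundle
        from Bio import SeqIO

        record = next(SeqIO.parse(str(directory / "synthetic_chrM.fa"), "fasta"))
        assert len(record.seq) == MT_LENGTH


def test_contradictory_noise_spec_rejected():
    with pytest.raises(ValueError, match="contradictory|below"):
        SimulationSpec.single_group(n=1, sequencing_error_vaf=0.2,
                                    somatic_vaf_range=(0.1, 0.9))
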