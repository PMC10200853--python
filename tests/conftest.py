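import pytest

from mtsomatic.synthetic_data import SimulationSpec, simulate_cohort
from mtsomatic.variant_filter import MtVariantCall


def make_call(**overrides) -> MtVariantCall:
    """A tumour SNV whose evidence sits comfortably inside every criterion."""
    fields = dict(
        sample_id="S1",
        position=1000,
        ref_allele="A",
        alt_allele="G",
        total_depth=1000,
        variant_reads=300,
        forward_variant_reads=150,
        variant_base_quality=32.0,
        mean_read_position=0.5,
        ref_read_length=150.0,
        var_read_length=150.0,
        ref_mapq=60.0,
        var_mapq=60.0,
        normal_context_fraction=0.95,
        ref_nm=1.0,
        var_nm=1.5,
    )
    fields.update(overrides)
    return MtVariantCall(**fields)


@pytest.fixture
def baseline_call():
    return make_call()


@pytest.fixture(scope="session")
def small_cohort():
    """Two-tumour cohort with a fixed somatic count; shared across tests."""
    spec = SimulationSpec.single_group(
        n=2, seed=7, n_true_somatic_per_tumour=3, n_germline_haplogroup=10,
        n_population_polymorphisms=4, n_noise_positions=5,
    )
    return simulate_cohort(spec)


@pytest.fixture(scope="session")
def small_bundle(small_cohort, tmp_path_factory):
    from mtsomatic.synthetic_data import write_fixture_bundle

    directory = tmp_path_factory.mktemp("bundle")
    manifest = write_fixture_bundle(small_cohort, directory)
    return directory, manifest
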