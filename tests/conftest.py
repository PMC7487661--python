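import pytest
from hypothesis import HealthCheck, settings

from tfnetminer import synth

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_config() -> synth.SynthConfig:
    """A fast, fully planted configuration for unit tests."""
    return synth.SynthConfig(
        seed=7,
        n_genes=200,
        frac_lncrna=0.25,
        chrom_length=1_000_000,
        n_samples_per_group=5,
        n_planted_de=30,
        n_planted_targets=12,
        n_decoy_peaks=25,
        pool_size=60,
        n_cofactor_profiles=4,
        module_spec=[(14, 2), (12, 1)],
    )


@pytest.fixture(scope="session")
def small_annotation(small_config):
    return synth.make_annotation(small_config)


@pytest.fixture(scope="session")
def small_expression(small_config, small_annotation):
    return synth.make_expression(small_config, small_annotation)


@pytest.fixture(scope="session")
def small_chip(small_config, small_annotation, small_expression):
    _, de_truth = small_expression
    planted = synth.pick_planted_targets(small_config, small_annotation, de_truth)
    peaks, pool, genome = synth.make_chip_data(small_config, small_annotation, planted)
    return planted, peaks, pool, genome
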