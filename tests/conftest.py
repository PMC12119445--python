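import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")

from sdrscan import SimConfig, simulate_genome, simulate_samples  # noqa: E402

#: quick desk-scale geometry used by most fixtures (seconds, not minutes)
SMALL = SimConfig(
    n_autosomes=2, autosome_length=400_000, sex_chrom_length=200_000,
    sdr_start=50_000, sdr_end=190_000, bin_size=5_000, snp_density=0.004,
    seed=7)


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    return SMALL


@pytest.fixture(scope="session")
def small_genome(small_cfg):
    return simulate_genome(small_cfg)


@pytest.fixture(scope="session")
def small_samples(small_genome, small_cfg):
    return simulate_samples(small_genome, small_cfg)
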