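import pytest

from ma_mutkit.genome import GenomeSpec, generate_reference


@pytest.fixture(scope="session")
def small_reference():
    """2 x 100 kb genome used by most tests."""
    return generate_reference(GenomeSpec(n_chromosomes=2, chrom_length=100_000, seed=7))


@pytest.fixture(scope="session")
def megabase_reference():
    """2 x 500 kb genome for rate-recovery and spectrum experiments."""
    return generate_reference(GenomeSpec(n_chromosomes=2, chrom_length=500_000, seed=11))
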