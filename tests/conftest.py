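import pytest

from levigene.synthetic import SyntheticConfig, generate_genome


@pytest.fixture(scope="session")
def truth_internal():
    """Default synthetic genome: lysis ORF buried inside replicase."""
    return generate_genome(SyntheticConfig(lysis_mode="replicase_internal"), seed=1)


@pytest.fixture(scope="session")
def truth_junction():
    return generate_genome(
        SyntheticConfig(lysis_mode="coat_replicase_junction"), seed=3
    )


@pytest.fixture(scope="session")
def truth_five_prime():
    return generate_genome(SyntheticConfig(lysis_mode="five_prime"), seed=2)
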