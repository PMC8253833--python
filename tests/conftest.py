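import pytest

from ctcflow.simulate import SyntheticSpec, generate_cohort, generate_two_group


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort, shared read-only across tests."""
    return generate_cohort(SyntheticSpec(seed=11))


@pytest.fixture(scope="session")
def two_group():
    """20-vs-20 two-group design with 100 planted DE genes (|log2FC| = 2)."""
    return generate_two_group(seed=11, n_genes=1500, n_de=50)
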