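import pytest

from codonbias import (
    SyntheticSpec,
    count_codons,
    generate,
    load_fixture,
    rscu,
)


@pytest.fixture(scope="session")
def citxet():
    """Payload of the per-gene (CitXET) count fixture."""
    return load_fixture("citxet_counts").payload


@pytest.fixture(scope="session")
def citxet_profile(citxet):
    return rscu(citxet["counts"])


@pytest.fixture(scope="session")
def xet20():
    """Payload of the pooled 20-gene count fixture."""
    return load_fixture("xet20_counts").payload


@pytest.fixture(scope="session")
def table1():
    """Published per-gene index matrix (20 rows) as a DataFrame."""
    return load_fixture("table1_indices").payload


@pytest.fixture(scope="session")
def synthetic_genes():
    """Default 20-gene synthetic set, fixed seed."""
    return generate(SyntheticSpec(seed=11))


@pytest.fixture(scope="session")
def synthetic_counts(synthetic_genes):
    return [count_codons(g) for g in synthetic_genes]
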