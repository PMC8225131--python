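import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from mitochar import (GeneratorParams, generate_genome_set,
                      generate_mitogenome, load_ancestral_order,
                      load_study_annotations, load_study_table)


@pytest.fixture(scope="session")
def default_genome():
    """One synthetic annotated mitogenome with its truth record."""
    return generate_mitogenome(GeneratorParams(seed=1))


@pytest.fixture(scope="session")
def genome_set():
    """Three genomes diverged from a common ancestor at rate 0.05."""
    return generate_genome_set(3, GeneratorParams(seed=5))


@pytest.fixture(scope="session")
def study_annotations():
    return load_study_annotations()


@pytest.fixture(scope="session")
def study_table():
    return load_study_table()


@pytest.fixture(scope="session")
def ancestral_order():
    return load_ancestral_order()
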