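import pytest

from polyfam.family_identification import identify_family
from polyfam.synthetic_data import FamilySimulationConfig, generate_family_genome


@pytest.fixture(scope="session")
def genome():
    """A seed-fixed synthetic polyploid genome with 10 planted groups."""
    return generate_family_genome(FamilySimulationConfig(seed=7, n_groups=10))


@pytest.fixture(scope="session")
def catalog(genome):
    return identify_family(
        genome.proteins,
        genome.queries,
        genome.features,
        transcript_parents=genome.transcripts,
        prefix="FAM",
    )
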