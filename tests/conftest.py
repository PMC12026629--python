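import pytest
from hypothesis import settings

from mitokit import reference
from mitokit.genome_model import AnnotatedGenome, CircularGenome
from mitokit.synthetic_data import GenomeSimSpec, simulate_genome

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_sim():
    """One simulated mitogenome with the published layout, plus its truth
    manifest (seeded, so identical across the whole session)."""
    return simulate_genome(GenomeSimSpec.default(seed=1))


@pytest.fixture(scope="session")
def reference_annotation():
    """The published gene arrangement over a placeholder sequence — enough
    for every statistic that depends only on coordinates."""
    return AnnotatedGenome(
        genome=CircularGenome("A" * reference.GENOME_LENGTH),
        features=reference.gene_features(),
    )
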