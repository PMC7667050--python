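import numpy as np
import pytest

from repeatome.simulate import (
    GenomeComponent,
    GenomeSpec,
    ReadSimParams,
    RepeatFamily,
    build_parental_genome,
    comparative_parent_specs,
    random_consensus,
    simulate_reads,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_parent_specs():
    """Desk-scale parental pair (300 kb) for fast clustering tests."""
    return comparative_parent_specs(genome_length=300_000)


@pytest.fixture(scope="session")
def small_parent_genome(small_parent_specs):
    return build_parental_genome(small_parent_specs[0], seed=11)


@pytest.fixture(scope="session")
def small_reads(small_parent_genome):
    """~400 reads at 0.2x from the small parent genome."""
    return simulate_reads(
        small_parent_genome, ReadSimParams(coverage=0.2), seed=21, sample="A"
    )


@pytest.fixture()
def two_family_spec(rng):
    """Two unrelated 6 kb families, 6 copies each, plus background."""
    fam1 = RepeatFamily("famX", "Ty1/Copia:SIRE", random_consensus(6000, rng))
    fam2 = RepeatFamily("famY", "Ty3/Gypsy:chromovirus/Tekay", random_consensus(6000, rng))
    return GenomeSpec(
        "twofam",
        (
            GenomeComponent(fam1, 6, 0.02),
            GenomeComponent(fam2, 6, 0.02),
        ),
        background_length=80_000,
    )
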