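"""Shared fixtures: one default synthetic mitogenome reused across modules."""

import pytest

from mitochar import GenomeSpec, generate_genome


@pytest.fixture(scope="session")
def default_genome():
    """A default-spec synthetic mitogenome (seed 1): (MitoGenome, FeatureTable)."""
    return generate_genome(GenomeSpec(seed=1))


@pytest.fixture(scope="session")
def genome(default_genome):
    return default_genome[0]


@pytest.fixture(scope="session")
def ftable(default_genome):
    return default_genome[1]
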