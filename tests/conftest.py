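"""Shared synthetic fixtures, generated at session scope to keep the suite fast."""

import pytest

from dfpmaa import make_registry, make_toy_genome, simulate_reads


@pytest.fixture(scope="session")
def registry():
    """30 toy HMMs with lengths spanning the coverage-gate-sensitive range."""
    return make_registry(30, seed=1, length_range=(40, 200))


@pytest.fixture(scope="session")
def genome_and_annotation(registry):
    return make_toy_genome(registry, n_segments_per_hmm=2, seed=2)


@pytest.fixture(scope="session")
def genome(genome_and_annotation):
    return genome_and_annotation[0]


@pytest.fixture(scope="session")
def annotation(genome_and_annotation):
    return genome_and_annotation[1]


@pytest.fixture(scope="session")
def reads(genome):
    return simulate_reads(genome, 5000, 250, seed=3)
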