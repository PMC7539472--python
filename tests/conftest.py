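import pytest

from mutsim import FixtureSpec, build_transcription_map, make_genes, make_genome


@pytest.fixture(scope="session")
def medium_spec():
    return FixtureSpec(chrom_lengths=(30_000, 30_000), n_mutations=800, seed=3)


@pytest.fixture(scope="session")
def medium_genome(medium_spec):
    return make_genome(medium_spec)


@pytest.fixture(scope="session")
def medium_genes(medium_spec, medium_genome):
    return make_genes(medium_spec, medium_genome)


@pytest.fixture(scope="session")
def medium_tmap(medium_genome, medium_genes):
    return build_transcription_map(medium_genome, medium_genes)


@pytest.fixture(scope="session")
def small_spec():
    return FixtureSpec(chrom_lengths=(8_000,), n_mutations=150, seed=4)


@pytest.fixture(scope="session")
def small_genome(small_spec):
    return make_genome(small_spec)
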