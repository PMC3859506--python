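import pytest

from aerobiome import synthetic as syn


@pytest.fixture(scope="session")
def community():
    return syn.default_community()


@pytest.fixture(scope="session")
def genomes(community):
    return syn.generate_genomes(community, seed=101)


@pytest.fixture(scope="session")
def reads_and_truth(community, genomes):
    return syn.simulate_reads(community, genomes, 600, seed=202)
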