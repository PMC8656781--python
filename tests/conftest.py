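import pytest

from methylseas import SimConfig, generate_genome, generate_manifest, generate_paired_betas


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig(seed=3)


@pytest.fixture(scope="session")
def genome(sim_config):
    return generate_genome(sim_config)


@pytest.fixture(scope="session")
def manifest(sim_config, genome):
    _, islands, gene_models = genome
    return generate_manifest(sim_config, islands, gene_models)


@pytest.fixture(scope="session")
def paired_betas(sim_config, manifest):
    return generate_paired_betas(manifest, sim_config)
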