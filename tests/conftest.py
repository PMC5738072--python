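import pytest

from gliascan.synthetic import (
    SyntheticConfig,
    generate_clone_library,
    generate_gene_family,
)


@pytest.fixture(scope="session")
def default_family():
    """Reference gene family: 18/12/19 templates with planted epitopes."""
    cfg = SyntheticConfig()
    genes, truth = generate_gene_family(cfg)
    return cfg, genes, truth


@pytest.fixture(scope="session")
def noisy_libraries(default_family):
    """Clone libraries at the published sizes with default noise rates."""
    cfg, _genes, truth = default_family
    libraries, clone_truth = generate_clone_library(truth, cfg)
    return cfg, libraries, clone_truth


@pytest.fixture(scope="session")
def zero_noise_libraries():
    cfg = SyntheticConfig.zero_noise()
    genes, truth = generate_gene_family(cfg)
    libraries, clone_truth = generate_clone_library(truth, cfg)
    return cfg, genes, truth, libraries, clone_truth
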