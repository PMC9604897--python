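import pytest

from pleurosim import SyntheticConfig, assign_all, build_fruiting_model, generate_model, to_reaction_graph


@pytest.fixture(scope="session")
def fruiting_model():
    return build_fruiting_model()


@pytest.fixture(scope="session")
def fruiting_graph(fruiting_model):
    return to_reaction_graph(fruiting_model)


@pytest.fixture(scope="session")
def fruiting_laws(fruiting_model):
    return assign_all(fruiting_model)


@pytest.fixture(scope="session")
def small_synthetic():
    return generate_model(SyntheticConfig(n_genes=3, n_extra_molecules=4, n_phenotypes=1, seed=11))
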