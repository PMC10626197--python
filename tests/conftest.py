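import numpy as np
import pytest

import synergyloop as sl


@pytest.fixture(scope="session")
def small_config():
    """A compact network configuration used throughout the suite.

    Dimensions are scaled down from the production defaults so that training
    on synthetic studies takes seconds; the architecture (encoder, symmetric
    bilinear pairing, head, early stopping) is identical.
    """
    return sl.RecoverConfig(
        single_hidden_dims=[64],
        drug_embedding_dim=16,
        bilinear_dim=8,
        combination_hidden_dims=[8],
        batch_size=32,
        learning_rate=1e-3,
        weight_decay=1e-4,
        max_epochs=150,
        patience=15,
    )


@pytest.fixture(scope="session")
def tiny_config():
    return sl.RecoverConfig(
        single_hidden_dims=[16],
        drug_embedding_dim=8,
        bilinear_dim=4,
        combination_hidden_dims=[4],
        batch_size=16,
        learning_rate=1e-3,
        weight_decay=0.0,
        max_epochs=60,
        patience=10,
    )


@pytest.fixture(scope="session")
def small_study():
    """A 20-drug synthetic study shared by read-only tests."""
    return sl.generate_study(sl.LandscapeParams(n_drugs=20, seed=11))


@pytest.fixture(scope="session")
def small_features(small_study):
    return sl.assemble_drug_features(small_study.library)


@pytest.fixture(scope="session")
def trained_small_model(small_study, small_features, small_config):
    model, report = sl.train_model(
        small_study.observed_records(), small_config, small_features, seed=0
    )
    return model, report


def make_block(inhibition, conc_a=None, conc_b=None, drug_a="A", drug_b="B"):
    inh = np.asarray(inhibition, dtype=float)
    na, nb = inh.shape[-2], inh.shape[-1]
    if conc_a is None:
        conc_a = np.arange(na, dtype=float)
    if conc_b is None:
        conc_b = np.arange(nb, dtype=float)
    return sl.DoseResponseBlock(drug_a, drug_b, "MCF7", conc_a, conc_b, inh)
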