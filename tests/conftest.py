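import pytest

from photoyield import (
    ELECTRONIC_COLUMNS,
    FeatureSpec,
    GeneratorConfig,
    assemble_features,
    explain,
    generate_dataset,
    train_model,
)

#: The descriptor set found best for energy-transfer reactions: scaled rates
#: plus HOMO energy, oscillator strength, singlet-triplet gap and dipole change.
BEST_SPEC = FeatureSpec(
    base_set="s_RC",
    auxiliary=("E_HOMO_eV", "f_S1", "dEST_eV", "dDM_debye"),
)


@pytest.fixture(scope="session")
def default_data():
    """The default synthetic campaign: 60 sensitizers x 5 reactions, seed 0."""
    return generate_dataset(GeneratorConfig(seed=0))


@pytest.fixture(scope="session")
def tiny_data():
    """8 sensitizers x 2 reactions — fast fixture for plumbing tests."""
    return generate_dataset(
        GeneratorConfig(n_sensitizers=8, reaction_ids=("CO-a", "CO-b"), seed=7)
    )


@pytest.fixture(scope="session")
def best_matrix(default_data):
    dataset, sensitizers = default_data
    return assemble_features(dataset, sensitizers, BEST_SPEC)


@pytest.fixture(scope="session")
def trained_model(best_matrix):
    return train_model(best_matrix, seed=0)


@pytest.fixture(scope="session")
def explanations(trained_model, best_matrix):
    """Every row of the default dataset explained against the full matrix."""
    return explain(trained_model, best_matrix.X, best_matrix.X)


@pytest.fixture(scope="session")
def full_spec():
    return FeatureSpec(base_set="s_RC", auxiliary=ELECTRONIC_COLUMNS)
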