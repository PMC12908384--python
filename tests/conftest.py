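import pytest

from doublebind import (
    ExperimentDesign,
    FitConfig,
    NoiseModel,
    generate_dataset,
    load_table1_fixture,
    staged_fit,
)


@pytest.fixture(scope="session")
def table1():
    return load_table1_fixture()


@pytest.fixture(scope="session")
def one_rep_design():
    return ExperimentDesign(n_replicates=1)


@pytest.fixture(scope="session")
def noiseless_ds(table1, one_rep_design):
    """One noiseless replicate of all four arms from the packaged truth."""
    return generate_dataset(
        table1.as_truth(), one_rep_design, NoiseModel(law="none", seed=1)
    )


@pytest.fixture(scope="session")
def staged_noiseless(noiseless_ds):
    """Staged fit of the noiseless dataset, shared across tests."""
    return staged_fit(noiseless_ds, FitConfig(n_multistart=2, seed=0))
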