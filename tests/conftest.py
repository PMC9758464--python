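import dataclasses

import pytest

from correctmem import code_trials, default_config, simulate_dataset, tabulate_mpt


@pytest.fixture(scope="session")
def e1_config():
    return default_config(1)


@pytest.fixture(scope="session")
def e2_config():
    return default_config(2)


@pytest.fixture(scope="session")
def e1_trials(e1_config):
    return simulate_dataset(e1_config, design_seed=7)


@pytest.fixture(scope="session")
def e2_trials(e2_config):
    return simulate_dataset(e2_config, design_seed=7)


@pytest.fixture(scope="session")
def e1_coded(e1_trials):
    return code_trials(e1_trials)


@pytest.fixture(scope="session")
def e1_counts(e1_coded):
    return tabulate_mpt(e1_coded)


@pytest.fixture(scope="session")
def e1_posterior(e1_counts):
    from correctmem import fit_hierarchical
    from correctmem.design import correction_conditions

    return fit_hierarchical(e1_counts, correction_conditions(1))


@pytest.fixture(scope="session")
def small_config(e1_config):
    """Cheap 24-participant variant for model smoke tests."""
    return dataclasses.replace(e1_config, n_participants=24, seed=42)
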