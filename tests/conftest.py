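import pytest

from mesotherm import SyntheticConfig, generate_experiment
from mesotherm.oxygen import add_fluxes


@pytest.fixture(scope="session")
def default_experiment():
    """One default-design synthetic experiment (240 rows, 30 tanks)."""
    return generate_experiment(SyntheticConfig(seed=42))


@pytest.fixture(scope="session")
def experiment_with_fluxes(default_experiment):
    df, truth = default_experiment
    return add_fluxes(df), truth
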