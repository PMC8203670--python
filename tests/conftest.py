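import pytest

from shakebox import (
    GeneratorConfig,
    generate_exploration_trials,
    normalize_playtimes,
)


@pytest.fixture(scope="session")
def default_trials():
    """Synthetic cohort at generator defaults (96 children, 384 trials)."""
    return generate_exploration_trials(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def default_norm(default_trials):
    return normalize_playtimes(default_trials)


@pytest.fixture(scope="session")
def noiseless_trials():
    """Deterministic cohort: no trial noise, no child baseline variation."""
    return generate_exploration_trials(
        GeneratorConfig(seed=5, noise_sd=0.0, child_sd=0.0)
    )


@pytest.fixture(scope="session")
def noiseless_norm(noiseless_trials):
    return normalize_playtimes(noiseless_trials)
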