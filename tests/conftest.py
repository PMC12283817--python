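import pytest

from casefind import GeneratorConfig, default_params, generate_cohort


@pytest.fixture(scope="session")
def params():
    return default_params()


@pytest.fixture(scope="session")
def big_cohort():
    """A 100,000-woman cohort at the default (published-marginal) configuration."""
    return generate_cohort(GeneratorConfig(n_women=100_000, seed=0))


@pytest.fixture
def small_cohort():
    return generate_cohort(GeneratorConfig(n_women=2_000, seed=7))
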