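import pytest

from tadrive.fixtures import FixtureSpec, generate_fixtures, generate_sex_fixtures


@pytest.fixture(scope="session")
def mono_fixtures():
    """1000 seeded random monoecious (state, params) pairs."""
    return generate_fixtures(FixtureSpec(n_states=1000, seed=1))


@pytest.fixture(scope="session")
def sex_fixtures():
    """1000 seeded random androdioecious (state, params) pairs."""
    return generate_sex_fixtures(FixtureSpec(n_states=1000, seed=1))
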