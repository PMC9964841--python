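import pytest

from envolg import china2020, china2020_targets


@pytest.fixture(scope="session")
def base():
    """The China-2020 base-case (params, policy) pair."""
    return china2020()


@pytest.fixture(scope="session")
def base_params(base):
    return base[0]


@pytest.fixture(scope="session")
def base_policy(base):
    return base[1]


@pytest.fixture(scope="session")
def targets():
    return china2020_targets()
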