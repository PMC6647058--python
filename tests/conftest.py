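import pytest

from fallfinder import load_ruleset


@pytest.fixture(scope="session")
def published_rules():
    return load_ruleset("published")


@pytest.fixture(scope="session")
def extended_rules():
    return load_ruleset("extended")
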