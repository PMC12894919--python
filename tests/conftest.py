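import numpy as np
import pytest

from co2fix import builtin_ruleset


@pytest.fixture(scope="session")
def rules():
    return builtin_ruleset()


@pytest.fixture(scope="session")
def marker_universe(rules):
    """The 42 distinct marker KOs of the built-in rule set, sorted."""
    return sorted(rules.all_marker_kos)


@pytest.fixture
def rng():
    return np.random.default_rng(20260917)
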