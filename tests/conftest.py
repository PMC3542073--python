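import pytest

from glycosim.config import load_reference_config
from glycosim.fixtures import fixture_network
from glycosim.rules import load_rule_table

MAN9 = "Ma2Ma2Ma3(Ma2Ma3(Ma2Ma6)Ma6)Mb4GNb4GN"
GLC_MAN9 = "Ga3" + MAN9
MAN5 = "Ma3(Ma3(Ma6)Ma6)Mb4GNb4GN"


@pytest.fixture(scope="session")
def rules_by_index():
    return {r.index: r for r in load_rule_table()}


@pytest.fixture(scope="session")
def reference():
    return load_reference_config()


@pytest.fixture(scope="session")
def small_network():
    """Reduced-cutoff pruned network shared by kinetics/fitting tests."""
    return fixture_network(mass_cutoff=2600.0, prune_threshold=1e-4)


@pytest.fixture(scope="session")
def man9():
    return MAN9


@pytest.fixture(scope="session")
def man5():
    return MAN5
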