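import pytest

from emtnet import compile_rules, emt_core_network
from emtnet.synthetic import fixtures


@pytest.fixture(scope="session")
def emt_net():
    return emt_core_network()


@pytest.fixture(scope="session")
def emt_rules(emt_net):
    return compile_rules(emt_net)


@pytest.fixture(scope="session")
def bundle():
    return fixtures()
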