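import pytest

from bernet import build_ber_net, minimal_t_invariants, mct_sets


@pytest.fixture(scope="session")
def ber():
    """The BER fixture net and its manifest (built once per session)."""
    return build_ber_net()


@pytest.fixture(scope="session")
def ber_net(ber):
    return ber[0]


@pytest.fixture(scope="session")
def ber_manifest(ber):
    return ber[1]


@pytest.fixture(scope="session")
def ber_invariants(ber_net):
    return minimal_t_invariants(ber_net)


@pytest.fixture(scope="session")
def ber_mct(ber_invariants, ber_net):
    return mct_sets(ber_invariants, ber_net)
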