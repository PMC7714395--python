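import pytest

from rubiscoflux import apply_knockouts
from rubiscoflux.synth import ToyNetworkSpec, make_toy_model, toy_heterologous_spec


@pytest.fixture
def het():
    return toy_heterologous_spec()


@pytest.fixture
def wild_type():
    """Toy network without the Prk/rubisco detour (7 reactions)."""
    return make_toy_model(ToyNetworkSpec(include_heterologous=False))


@pytest.fixture
def full_toy():
    """Toy network with the detour present (9 reactions)."""
    return make_toy_model()


@pytest.fixture
def delta_rpi(full_toy):
    """Detour-bearing toy with the isomerase knocked out."""
    return apply_knockouts(full_toy, {"T5_rpi"})
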