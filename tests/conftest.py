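import pytest

from sepsisbn import SimConfig, load_tlr4, mono_screen
from sepsisbn.toys import make_toy_network


@pytest.fixture(scope="session")
def tlr4():
    return load_tlr4()


@pytest.fixture(scope="session")
def default_config():
    return SimConfig()  # 60 steps, 100 reps, random_order


@pytest.fixture(scope="session")
def mono_df(tlr4):
    """Default mono mediator screen, shared by screen and acceptance tests."""
    return mono_screen(tlr4, seed=1)


@pytest.fixture(scope="session")
def toy(request):
    return make_toy_network


@pytest.fixture()
def chain3():
    return make_toy_network(n=3, motif="chain")


@pytest.fixture()
def or_redundant():
    return make_toy_network(motif="or_redundant")
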