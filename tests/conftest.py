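import pytest

from motifroles import default_catalog, toy_graph

TOY_NAMES = ("two_path", "cycle3", "ffl", "recip_plus_out", "complete_triad")


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(params=TOY_NAMES)
def toy(request):
    return toy_graph(request.param)
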