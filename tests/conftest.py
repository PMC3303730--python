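import pytest

from zukerfold import RnaSequence, nussinov_params, simple_params


@pytest.fixture(scope="session")
def nussinov():
    return nussinov_params()


@pytest.fixture(scope="session")
def simple():
    return simple_params()


@pytest.fixture(scope="session", params=["nussinov", "simple"])
def params(request, nussinov, simple):
    return nussinov if request.param == "nussinov" else simple


@pytest.fixture
def hairpin_seq():
    """Three G-C pairs around an AAA loop; the canonical tiny fold."""
    return RnaSequence("hp", "GGGAAACCC")
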