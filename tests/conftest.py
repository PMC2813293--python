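import pytest

from tph2_isoedit import build_reference


@pytest.fixture(scope="session")
def model():
    """The default deterministic surrogate reference model."""
    return build_reference()


@pytest.fixture(scope="session")
def utr_len(model):
    return len(model.utr5_seq)
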