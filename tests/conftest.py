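import pytest

from tigsmm.synthetic import make_textbook_model


@pytest.fixture
def textbook():
    """Hand-written 10-reaction model: carbon in, two unit-yield parallel
    paths, a half-yield bypass, nutrient branch, biomass B + C."""
    return make_textbook_model()
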