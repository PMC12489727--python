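import pytest

from acylquin.structures import parse_descriptor


@pytest.fixture
def mdicqa():
    """1,5-dicaffeoyl-3-malonylquinic acid (the reference MDiCQA regioisomer)."""
    return parse_descriptor("QA[1:caf,3:mal,5:caf]")


@pytest.fixture
def dimdicqa():
    """1,5-dicaffeoyl-3,4-dimalonylquinic acid."""
    return parse_descriptor("QA[1:caf,3:mal,4:mal,5:caf]")


@pytest.fixture
def quercetin_malonyl_glucoside():
    """Quercetin-3-O-(6''-O-malonyl)-glucoside."""
    return parse_descriptor("QUE-3-Glc[6'':mal]")


@pytest.fixture
def luteolin_dimalonyl_glucoside():
    """Luteolin-7-O-(2'',6''-di-O-malonyl)-glucoside."""
    return parse_descriptor("LUT-7-Glc[2'':mal,6'':mal]")


@pytest.fixture
def kaempferol_malonyl_glucoside():
    """Kaempferol-3-O-(6''-O-malonyl)-glucoside (catechol-free)."""
    return parse_descriptor("KMP-3-Glc[6'':mal]")
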