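import pytest

from neudose import paper_fixtures


@pytest.fixture(scope="session")
def paper():
    """(measurements, depth-dose curve, organ table, coefficients, prescription)."""
    return paper_fixtures()


@pytest.fixture(scope="session")
def measurements(paper):
    return paper[0]


@pytest.fixture(scope="session")
def curve(paper):
    return paper[1]


@pytest.fixture(scope="session")
def organs(paper):
    return paper[2]


@pytest.fixture(scope="session")
def coefficients(paper):
    return paper[3]


@pytest.fixture(scope="session")
def prescription(paper):
    return paper[4]
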