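import numpy as np
import pytest

from necroscan.numbering import assign_generic_numbers, locate_anchors
from necroscan.synthetic import (
    HTAAR6_STANDIN_LAYOUT,
    HTAAR8_STANDIN_LAYOUT,
    SequenceSpec,
    ToyComplexConfig,
    make_sequences,
    make_toy_complex,
)


@pytest.fixture(scope="session")
def htaar_standins():
    """Synthetic hTAAR6/hTAAR8 stand-ins with the published residue layout."""
    return make_sequences([
        SequenceSpec(id="hTAAR6", layout=HTAAR6_STANDIN_LAYOUT,
                     species="Homo sapiens", subtype="TAAR6"),
        SequenceSpec(id="hTAAR8", layout=HTAAR8_STANDIN_LAYOUT,
                     species="Homo sapiens", subtype="TAAR8"),
    ], seed=0)


@pytest.fixture(scope="session")
def htaar6(htaar_standins):
    return htaar_standins[0]


@pytest.fixture(scope="session")
def htaar8(htaar_standins):
    return htaar_standins[1]


@pytest.fixture(scope="session")
def htaar6_numbering(htaar6):
    return assign_generic_numbers(htaar6, locate_anchors(htaar6))


@pytest.fixture(scope="session")
def htaar8_numbering(htaar8):
    return assign_generic_numbers(htaar8, locate_anchors(htaar8))


@pytest.fixture(scope="session")
def active_toy():
    """Active-like toy complex: 10.2 Å pocket, planted contact shell."""
    return make_toy_complex(ToyComplexConfig(carboxylate_distance=10.2))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
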