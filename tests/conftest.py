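import numpy as np
import pytest

from spinscape.fixtures import FixtureSpec, make_fixture


@pytest.fixture(scope="session")
def helix():
    """30-residue ideal helix: Cys at 6, dHis motif at 20/24."""
    return make_fixture(
        FixtureSpec(topology="helix", length=30, cys_sites=(6,), dhis_sites=((20, 24),))
    )


@pytest.fixture(scope="session")
def strand():
    """10-residue ideal strand with an i,i+2 dHis motif."""
    return make_fixture(
        FixtureSpec(topology="strand", length=10, cys_sites=(3,), dhis_sites=((4, 6),))
    )


@pytest.fixture(scope="session")
def two_chain():
    """Two strands 30 Å apart: a geometrically unbridgeable dHis pair."""
    return make_fixture(
        FixtureSpec(
            topology="two_chain", length=10, dhis_sites=((4, 6),), chain_separation=30.0
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
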