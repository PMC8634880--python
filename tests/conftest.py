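import numpy as np
import pytest

from cleavemap.io_formats import SequenceRecord
from cleavemap.synthetic_data import PanelConfig, make_fixture_panel


@pytest.fixture(scope="session")
def default_panel():
    """One default eight-substrate panel (seeded) shared across tests."""
    return make_fixture_panel(PanelConfig(master_seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240611)


@pytest.fixture()
def toy_protein_records():
    return [
        SequenceRecord("pA", "protein", "MKTAYIAKQR"),
        SequenceRecord("pB", "protein", "MKTAYIAKQR"),
    ]
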