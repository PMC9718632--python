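import pytest

from chromqc.synth import default_panel_design, make_batch_panel


@pytest.fixture(scope="session")
def default_sim():
    """One study-shaped simulated panel shared across tests."""
    return make_batch_panel(default_panel_design(seed=7))


@pytest.fixture(scope="session")
def default_design():
    return default_panel_design(seed=7)
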