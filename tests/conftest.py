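import pytest

from pepmatrix import build_pilot_matrix


@pytest.fixture(scope="session")
def pilot():
    """Default 6x6 pilot matrix library."""
    return build_pilot_matrix()
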