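import numpy as np
import pytest

from msrelevance import FieldSpec, generate_field


@pytest.fixture
def checkerboard4():
    """4x4 parity checkerboard, 8-bit."""
    return (np.add.outer(np.arange(4), np.arange(4)) % 2 * 255).astype(np.uint8)


@pytest.fixture(scope="session")
def field_h0_128():
    return generate_field(FieldSpec(H=0.0, size=(128, 128), seed=7))


@pytest.fixture(scope="session")
def field_hneg_128():
    return generate_field(FieldSpec(H=-0.8, size=(128, 128), seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
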