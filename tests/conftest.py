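import numpy as np
import pytest

from redqueen import ModelParams


@pytest.fixture
def baseline() -> ModelParams:
    """Two-heat baseline parameters (weak backdrop binding 99% of the dose)."""
    return ModelParams()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
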