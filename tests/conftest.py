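import numpy as np
import pytest

from ecdkit import BroadeningSettings, ConformerRecord, TransitionSet


@pytest.fixture
def settings():
    return BroadeningSettings()


@pytest.fixture
def separated_library():
    """Three conformers with well-separated single bands (205/245/285 nm)."""
    return [
        ConformerRecord("c-a", 0.1, TransitionSet([205.0], [12.0])),
        ConformerRecord("c-b", 0.7, TransitionSet([245.0], [-9.0])),
        ConformerRecord("c-c", 1.4, TransitionSet([285.0], [7.0])),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)
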