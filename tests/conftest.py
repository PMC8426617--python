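import numpy as np
import pytest

from touchtask.stimulus_space import build_feature_space, default_feature_space


@pytest.fixture(scope="session")
def space():
    return default_feature_space()


@pytest.fixture()
def tiny_space():
    """A (2,2,2,2) space: every dimension has one neutral and one non-neutral value."""
    return build_feature_space(
        [
            {"name": "body_shape", "values": ["n0", "a0"], "neutral": "n0"},
            {"name": "color", "values": ["n1", "a1"], "neutral": "n1"},
            {"name": "arm_type", "values": ["n2", "a2"], "neutral": "n2"},
            {"name": "surface_pattern", "values": ["n3", "a3"], "neutral": "n3"},
        ]
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
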