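import numpy as np
import pytest

from scidiscovery import Model, enumerate_space


@pytest.fixture(scope="session")
def space():
    return enumerate_space(3)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)


def model(label: str) -> Model:
    return Model.from_label(label)
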