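import numpy as np
import pytest

from fractagg import LambdaSchedule, grow


@pytest.fixture(scope="session")
def small_dla():
    """One small standard DLA cluster (lam = 1), reused across tests."""
    return grow("DLA", LambdaSchedule(1.0, 0.0), 400, record_every=10, seed=42)


@pytest.fixture(scope="session")
def small_ba():
    return grow("BA", LambdaSchedule(1.0, 0.0), 400, record_every=10, seed=42)


@pytest.fixture()
def rng():
    return np.random.RandomState(1234)


class ScriptedRNG:
    """Feeds a fixed sequence of uniforms to code expecting RandomState."""

    def __init__(self, values):
        self.values = list(values)

    def random_sample(self, *args):
        return self.values.pop(0)


@pytest.fixture()
def scripted_rng():
    return ScriptedRNG
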