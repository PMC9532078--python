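import numpy as np
import pytest


class ForcedRng:
    """Stand-in generator returning scripted values for targeted draw paths."""

    def __init__(
        self,
        random_value=0.0,
        normal_value=0.0,
        uniform_value=0.0,
        choice_values=None,
    ):
        self.random_value = random_value
        self.normal_value = normal_value
        self.uniform_value = uniform_value
        self.choice_values = choice_values

    def random(self, size=None):
        if size is None:
            return self.random_value
        return np.full(size, self.random_value)

    def standard_normal(self, size=None):
        if size is None:
            return self.normal_value
        return np.full(size, self.normal_value)

    def uniform(self, low=0.0, high=1.0, size=None):
        if size is None:
            return self.uniform_value
        return np.full(size, self.uniform_value)

    def choice(self, a, size=None, replace=True, p=None):
        return np.asarray(self.choice_values)


@pytest.fixture
def forced_rng_factory():
    return ForcedRng


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
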