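import numpy as np
import pytest


class StubRng:
    """Minimal Generator stand-in with pinned draws, for algebra tests.

    ``uniforms`` feeds successive ``random()`` calls; ``normal`` and
    ``integers`` return constants.
    """

    def __init__(self, uniforms=(), normal=1.0, integer=1, uniform_value=None):
        self._uniforms = list(uniforms)
        self._normal = normal
        self._integer = integer
        self._uniform_value = uniform_value

    def random(self, size=None):
        value = self._uniforms.pop(0) if self._uniforms else 0.0
        return value if size is None else np.full(size, value)

    def normal(self, loc=0.0, scale=1.0, size=None):
        value = loc + scale * self._normal
        return value if size is None else np.full(size, value)

    def integers(self, low, high=None, size=None):
        return self._integer if size is None else np.full(size, self._integer)

    def uniform(self, low=0.0, high=1.0, size=None):
        if self._uniform_value is not None:
            mid = self._uniform_value
        else:
            mid = (np.asarray(low) + np.asarray(high)) / 2.0
        if size is None:
            return mid
        return np.broadcast_to(mid, size).copy()


@pytest.fixture
def stub_rng_factory():
    return StubRng
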