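import numpy as np
import pytest


class StubRng:
    """Deterministic stand-in for numpy's Generator, fed from queues.

    Each supported method pops from its own queue; shapes are honored by
    padding/truncating the queued values where a size is requested.
    """

    def __init__(self, uniform=(), normal=(), integers=()):
        self._uniform = list(uniform)
        self._normal = list(normal)
        self._integers = list(integers)

    def _pop(self, queue, size):
        if size is None:
            return queue.pop(0)
        out = [queue.pop(0) for _ in range(int(np.prod(size)))]
        return np.array(out).reshape(size)

    def random(self, size=None):
        return self._pop(self._uniform, size)

    def standard_normal(self, size=None):
        return self._pop(self._normal, size)

    def integers(self, low, high, size=None):
        return self._pop(self._integers, size)


@pytest.fixture
def stub_rng_factory():
    return StubRng


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
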