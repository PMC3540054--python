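import numpy as np
import pytest

from phagepack import CapsidAssembly, InteractionParams, TailGeometry


@pytest.fixture
def params():
    return InteractionParams()


@pytest.fixture
def charged_params():
    return InteractionParams(charged=True)


@pytest.fixture
def assembly():
    return CapsidAssembly()


@pytest.fixture
def tailed_assembly():
    return CapsidAssembly(tail=TailGeometry())


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def make_chain(n, rng, spacing=0.95, jitter=0.12, offset=(0.0, 0.0, -5.0)):
    """Random valid chain: consecutive bonds near the FENE minimum."""
    steps = rng.normal(0.0, jitter, size=(n - 1, 3))
    steps[:, 2] += spacing
    pos = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
    return pos + np.asarray(offset)
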