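import numpy as np
import pytest

from nefsim import EnsembleSpec, LIFParams, ModelSpec, NodeSpec, connect, probe


@pytest.fixture
def lif():
    return LIFParams(50)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def two_ensemble_model():
    """A sine-driven pair of ensembles: A decodes sin of its input into B."""
    m = ModelSpec("pair", seed=3)
    stim = NodeSpec("stim", lambda t: np.array([np.sin(2 * np.pi * t)]), size_out=1)
    a = EnsembleSpec("A", LIFParams(60), 1)
    b = EnsembleSpec("B", LIFParams(60), 1)
    for obj in (stim, a, b):
        m.add(obj)
    m.add(connect(stim, a, name="in"))
    m.add(connect(a, b, function=np.sin, name="ab"))
    m.add(connect(b, b, name="rec"))
    p = probe(b, "decoded_output", filter_tau=0.01, name="pb")
    m.add(p)
    return m, p
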