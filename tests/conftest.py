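import numpy as np
import pytest

from flowcircuit import ModelConfig, build_phantom


@pytest.fixture(scope="session")
def phantom_spec():
    return build_phantom(0)


@pytest.fixture()
def config():
    return ModelConfig()


def random_instance(rng, n_max=4, m_max=2, zero_frac=0.3):
    """Random feasible model instance: symmetric weights + nonneg activations."""
    n = int(rng.integers(2, n_max + 1))
    m = int(rng.integers(1, m_max + 1))
    w = rng.uniform(0.0, 100.0, size=(n, n))
    w[rng.random((n, n)) < zero_frac] = 0.0
    w = np.triu(w, 1)
    w = w + w.T
    if w.max() == 0:
        w[0, 1] = w[1, 0] = 50.0
    r = rng.uniform(0.0, 2.0, size=(n, m))
    r[rng.random((n, m)) < zero_frac] = 0.0
    return w, r
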