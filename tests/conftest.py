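import numpy as np
import pytest

import cyclesynth as cs


def numeric_gradient(f, array, eps: float = 1e-6) -> np.ndarray:
    """Central finite differences of scalar f() w.r.t. `array` (in place)."""
    grad = np.zeros_like(array)
    it = np.nditer(array, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        orig = array[idx]
        array[idx] = orig + eps
        fp = f()
        array[idx] = orig - eps
        fm = f()
        array[idx] = orig
        grad[idx] = (fp - fm) / (2 * eps)
    return grad


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_manifest():
    """14 train + 4 test registered 48x48 phantom pairs (fast smoke scale)."""
    man = cs.generate_dataset(10, 2, cs.PhantomConfig(size=(48, 48)),
                              master_seed=7)
    return man


@pytest.fixture(scope="session")
def tiny_gen_config():
    return cs.GeneratorConfig(base_channels=8)
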