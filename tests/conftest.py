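import warnings

import numpy as np
import pytest

from arterysim import experiments as exp


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_rotation(rng):
    """Proper-orthogonal 3x3 matrix from a random quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def random_minor_symmetric(rng):
    t = rng.normal(size=(3, 3, 3, 3))
    t = 0.5 * (t + np.swapaxes(t, 0, 1))
    return 0.5 * (t + np.swapaxes(t, 2, 3))


@pytest.fixture(scope="session")
def tiny_config():
    return exp.generate_fixture("tiny")


@pytest.fixture(scope="session")
def tiny_s_test_run(tiny_config):
    """One short stretching test at 20 mmHg on the tiny mesh, reused widely."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return exp.run_s_test(tiny_config, pressure_mmHg=20.0, stretch_max=1.6)
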