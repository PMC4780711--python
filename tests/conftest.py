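import numpy as np
import pytest

from dsdesign.families import DetectionFamily, half_normal, hazard_rate


@pytest.fixture
def hn() -> DetectionFamily:
    return half_normal()


@pytest.fixture
def hr() -> DetectionFamily:
    return hazard_rate()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20160307)


def conditional_draws(family, theta, size, rng, batch=None):
    """Rejection sampler from the detection-conditional distance density:
    propose U(0, w), accept with probability g(d)."""
    batch = batch or 4 * size
    out = []
    total = 0
    while total < size:
        d = rng.uniform(0.0, family.w, size=batch)
        keep = d[rng.random(batch) < family.g(d, theta)]
        out.append(keep)
        total += keep.size
    return np.concatenate(out)[:size]


def random_theta(family, rng):
    """A random valid parameter draw covering a broad practical range."""
    if family.n_params == 1:
        return np.array([rng.uniform(0.1, 3.0)])
    return np.array([rng.uniform(0.1, 3.0), rng.uniform(1.05, 5.0)])
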