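import numpy as np
import pytest

import gpcpk as g


@pytest.fixture(scope="session")
def dog1():
    """Reference canine metformin GPC parameter set."""
    return g.dog1_params()


@pytest.fixture(scope="session")
def dog1_model():
    return g.dog1_model()


@pytest.fixture(scope="session")
def policy30():
    return g.PrecisionPolicy(target_digits=30)


@pytest.fixture(scope="session")
def policy65():
    return g.PrecisionPolicy(target_digits=65)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_params(rng, n):
    """Admissible GPC parameter draws for property sweeps (alpha kept away
    from integers, beta small as in bolus-disposition practice)."""
    out = []
    while len(out) < n:
        a = rng.uniform(0.2, 1.2)
        b = rng.uniform(0.3, 25.0)
        alpha = rng.uniform(0.1, 1.9)
        if abs(alpha - round(alpha)) < 0.03:
            continue
        beta = rng.uniform(1e-3, 1e-2)
        out.append(g.GPCParams(a, b, alpha, beta))
    return out
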