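import numpy as np
import pytest

import dualhomeo as dh


@pytest.fixture(scope="session")
def lin():
    return dh.linear()


@pytest.fixture(scope="session")
def quad():
    return dh.quadratic(c2=1.0)


@pytest.fixture(scope="session")
def canonical_cfg(lin, quad):
    """Linear intrinsic / quadratic synaptic control, targets 2.5 < 3.5."""
    return dh.DualControlConfig(fa=lin, fb=quad, r_a=2.5, r_b=3.5)


@pytest.fixture(scope="session")
def white_unit():
    """OU rate unit with unit-amplitude white input (C = 1), tau_r = 0.5."""
    return dh.OURateUnit(
        tau_r=0.5, input=dh.StationaryInput(kind="white", phi=1.0, sigma=1.0))


def random_quadratic_pair(rng):
    """A random admissible quadratic control pair plus targets."""
    while True:
        r_a, r_b = np.sort(rng.uniform(1.0, 5.0, 2))
        if r_b - r_a < 0.2:
            continue
        c1a, c1b = rng.uniform(0.5, 2.0, 2)
        c2a, c2b = rng.uniform(-0.2, 0.5, 2)
        fa = dh.quadratic(0.0, c1a, c2a)
        fb = dh.quadratic(0.0, c1b, c2b)
        # admissibility: increasing at both targets
        if min(fa.df(r_a), fa.df(r_b), fb.df(r_a), fb.df(r_b)) <= 0.05:
            continue
        return fa, fb, float(r_a), float(r_b)
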