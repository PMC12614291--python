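import numpy as np
import pytest

from cbctdiff.schedules import make_schedule


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def linear1000():
    return make_schedule("linear", 1000, 1e-4, 0.02)


@pytest.fixture(scope="session")
def cosine1000():
    return make_schedule("cosine", 1000, 1e-4, 0.02)


@pytest.fixture(scope="session")
def sigmoid1000():
    return make_schedule("sigmoid", 1000, 1e-4, 0.02)


class OracleDenoiser:
    """Exact noise oracle targeting a fixed clean image x0*.

    Inverts the one-shot forward map: eps = (x_t - sqrt(ab_t) x0) /
    sqrt(1 - ab_t).  Plugged into the ancestral update it contracts the
    residual x_t - sqrt(ab_t) x0 at every step and lands on x0 exactly.
    """

    def __init__(self, x0, schedule):
        self.x0 = np.asarray(x0, dtype=np.float64)
        self.schedule = schedule

    def predict(self, x_t, y0, t):
        ab = self.schedule.alpha_bar[int(t)]
        return (np.asarray(x_t) - np.sqrt(ab) * self.x0) / np.sqrt(1.0 - ab)


@pytest.fixture
def oracle_denoiser_factory():
    return OracleDenoiser
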