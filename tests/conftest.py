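import numpy as np
import pytest

from mupoolsim import (excitation_signal, fit_pool_twitches,
                       generate_pool_firings, load_pool, recruitment_plan)


@pytest.fixture(scope="session")
def pool():
    return load_pool("builtin")


@pytest.fixture(scope="session")
def excitation():
    # plateau covering the whole analysed 2000-4000 ms window
    return excitation_signal(plateau_ms=3000)


@pytest.fixture(scope="session")
def plan(pool):
    return recruitment_plan(pool)


@pytest.fixture(scope="session")
def ns_firings(pool, excitation, plan):
    return generate_pool_firings(pool, excitation, plan, seed=1)


@pytest.fixture(scope="session")
def twitches(pool):
    return fit_pool_twitches(pool)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)
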