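import numpy as np
import pytest

from lipsfft import (ChargeSystem, SplitPotential, get_potential,
                     random_neutral_system)

BOX = (4.0, 4.0, 4.0)


@pytest.fixture(params=["null", "rf", "poly5"])
def split_potential(request):
    """One SplitPotential per shipped reaction-field plug-in."""
    if request.param == "poly5":
        pot = get_potential("poly5", coefficients=[-1.2, 0.0, 0.3, 0.0, 0.0, 0.1])
    else:
        pot = get_potential(request.param)
    return SplitPotential(pot, r_c=1.0, R_c=2.0)


@pytest.fixture
def rf_split():
    return SplitPotential(get_potential("rf"), r_c=1.0, R_c=2.0)


@pytest.fixture
def neutral64():
    return random_neutral_system(64, BOX, seed=11)


@pytest.fixture
def small_random_system():
    rng = np.random.default_rng(42)
    pos = rng.uniform(0, 1, (20, 3)) * np.asarray(BOX)
    q = rng.normal(size=20)
    q -= q.mean()
    return ChargeSystem(pos, q, BOX)
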