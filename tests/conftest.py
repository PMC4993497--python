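import numpy as np
import pytest

import biodyn as b


@pytest.fixture
def schedule_36d():
    """Twelve 3-day renewal intervals over 36 days, fluctuating forcing."""
    rng = np.random.default_rng(2024)
    concs = rng.uniform(40.0, 120.0, size=12)
    return b.ExposureSchedule.regular(36.0, 3.0, concs)


@pytest.fixture
def pb_like_params():
    """Rate constants derived from a 10 g fish and covalent index 6."""
    return b.derive_params(10.0, 6.0, g=0.015, kp=1.36e-3)


@pytest.fixture
def infected_system():
    load = b.ParasiteLoad(n_parasites=5, Wp0=0.008, gp=0.021, Cp0=0.0)
    return b.HostParasiteSystem(fish=b.FishState(C0=0.0, W0=10.0), load=load)


def random_uninfected_configs(n, rng):
    """Random valid (schedule-concs, ku, lam, c0) tuples on the 36 d grid."""
    concs = rng.uniform(0.0, 150.0, size=(n, 12))
    ku = rng.uniform(1e-4, 1e-2, size=n)
    lam = rng.uniform(0.01, 0.5, size=n)
    c0 = rng.uniform(0.0, 5.0, size=n)
    return concs, ku, lam, c0
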