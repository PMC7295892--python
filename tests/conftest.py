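import numpy as np
import pytest

from rivaldyn.forcing import ForcingSpec
from rivaldyn.model import ModelParams


@pytest.fixture(scope="session")
def fixed_spec():
    return ForcingSpec(protocol="fixed", J_max=10.0)


@pytest.fixture(scope="session")
def swap_spec():
    return ForcingSpec(protocol="swap", f_s=1.5, J_max=10.0)


@pytest.fixture(scope="session")
def flicker_spec():
    return ForcingSpec(protocol="flicker", f_s=1.5, flicker_multiple=12, J_max=10.0)


@pytest.fixture(scope="session")
def riv_trajectory(fixed_spec):
    """Settled rivalry-oscillation trajectory at (g, h) = (1.5, 4.3), reused
    by several tests."""
    from rivaldyn.integrate import default_ic, settle

    p = ModelParams(g=1.5, h=4.3, gain_mode="smoothed")
    traj = settle(p, fixed_spec, default_ic(p), t_transient=30_000.0,
                  t_record=40_000.0, record_stride=10)
    return p, traj


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
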