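import numpy as np
import pytest

import myosyn as ms

CRANK_SEED = 1


@pytest.fixture(scope="session")
def forearm():
    return ms.forearm_model()


@pytest.fixture(scope="session")
def forearm_table(forearm):
    return ms.build_synergy_table(forearm)


@pytest.fixture(scope="session")
def crank():
    return ms.make_crank_model(CRANK_SEED)


@pytest.fixture(scope="session")
def crank_table(crank):
    return ms.build_synergy_table(crank)


@pytest.fixture()
def simple_muscle():
    """One flexor with constant moment arm 0.03 m, optimal fiber at theta=1."""
    r = 0.03
    l_opt, l_slack = 0.10, 0.20
    c0 = l_opt + l_slack + r * 1.0
    return ms.MuscleParams(
        name="simple",
        f0max=100.0,
        pennation=0.0,
        length_poly=[c0, -r],
        l_opt=l_opt,
        l_slack=l_slack,
        v_max=10.0,
    )


@pytest.fixture()
def simple_model(simple_muscle):
    """Single-muscle plant with no gravity and no damping."""
    extensor = ms.MuscleParams(
        name="simple_ext",
        f0max=100.0,
        pennation=0.0,
        length_poly=[0.28, 0.02],
        l_opt=0.10,
        l_slack=0.16,
        v_max=10.0,
    )
    return ms.OneDoFModel(
        muscles=[simple_muscle, extensor],
        inertia=0.05,
        damping=0.0,
        gravity_torque=None,
        theta_range=(0.0, 2.0),
        name="simple",
        meta={"rep_pos": 0, "rep_neg": 1},
    )
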