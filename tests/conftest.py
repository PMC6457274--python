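import numpy as np
import pytest

import handleprop as hp

#: the published optimized shape parameters (A m, B m, n, beta deg)
PRINTED_SHAPE = dict(A=0.151, B=0.152, n=0.700, beta_deg=15.95)


@pytest.fixture(scope="session")
def printed_shape() -> hp.PathShapeParams:
    return hp.PathShapeParams.from_degrees(**PRINTED_SHAPE)


@pytest.fixture(scope="session")
def roster() -> hp.MuscleRoster:
    return hp.MuscleRoster.default()


@pytest.fixture(scope="session")
def arm_cfg() -> hp.ArmConfig:
    return hp.ArmConfig()


@pytest.fixture(scope="session")
def mech_cfg() -> hp.MechanismConfig:
    return hp.MechanismConfig()


@pytest.fixture(scope="session")
def circle_profile() -> hp.CrankLengthProfile:
    return hp.CrankLengthProfile.from_radius(0.12)


@pytest.fixture(scope="session")
def trace_low_excitation(circle_profile, roster, arm_cfg, mech_cfg):
    """Steady 5% excitation of all 15 muscles on a circular path."""
    return hp.simulate_cycles(
        circle_profile,
        hp.constant_excitation(np.full(len(roster), 0.05)),
        roster,
        arm_cfg,
        mech_cfg,
    )


@pytest.fixture(scope="session")
def trace_phased(circle_profile, roster, arm_cfg, mech_cfg, mech_period):
    """A crudely phased excitation pattern that produces nonzero power:
    shoulder flexors drive the first half cycle, extensors the second."""
    from handleprop.optimize import ExcitationSplines

    rng = np.random.default_rng(7)
    nodes = 0.05 + 0.45 * rng.random((len(roster), 6))
    return hp.simulate_cycles(
        circle_profile,
        ExcitationSplines(nodes, cycle=mech_period),
        roster,
        arm_cfg,
        mech_cfg,
    )


@pytest.fixture(scope="session")
def mech_period(mech_cfg) -> float:
    return mech_cfg.period
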