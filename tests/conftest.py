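import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gaitbalance.anthropometry import build_subject_model
from gaitbalance.dynamics import PendulumParams
from gaitbalance.gait_phase import detect_phases
from gaitbalance.identification import fit_controller, segment_trials
from gaitbalance.synthetic_data import WalkScenario, simulate_walk

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

# The controller parameters identified for the stepping/braking studies:
# eigenvalue product constraint 8.67 1/s^2 with zeta1 = 4 -> zeta2 = 2.1675.
ZETA1_TRUE = 4.0
CONSTRAINT = 8.67
ZETA2_TRUE = CONSTRAINT / ZETA1_TRUE


@pytest.fixture(scope="session")
def subject():
    return build_subject_model(1.65, 57.0)


@pytest.fixture(scope="session")
def params():
    return PendulumParams(zeta1=ZETA1_TRUE, zeta2=ZETA2_TRUE, z_com=0.94)


@pytest.fixture(scope="session")
def stepping_sim():
    """Noiseless stepping-and-braking trial at the identified parameters."""
    return simulate_walk(WalkScenario(kind="stepping", n_steps=1, noise_level=0.0))


@pytest.fixture(scope="session")
def walk_sim():
    """Noiseless 6-step straight walk with the default gait timing."""
    return simulate_walk(WalkScenario(kind="straight_walk", n_steps=6, noise_level=0.0))


@pytest.fixture(scope="session")
def noisy_walk_sim():
    return simulate_walk(WalkScenario(kind="straight_walk", n_steps=6, noise_level=1.0, seed=7))


@pytest.fixture(scope="session")
def walk_detection(walk_sim):
    return detect_phases(walk_sim.recording, walk_sim.subject)


@pytest.fixture(scope="session")
def stepping_fit(stepping_sim):
    segments = segment_trials(stepping_sim.timelines)
    return fit_controller(
        stepping_sim.recording, segments, constraint_product=CONSTRAINT, seed=0
    )


@pytest.fixture(scope="session")
def noisy_recovery():
    """Constrained fits on 20 noisy stepping trials (median-recovery data)."""
    z1, z2, xp_err = [], [], []
    for seed in range(20):
        res = simulate_walk(
            WalkScenario(kind="stepping", n_steps=1, noise_level=1.0, seed=seed)
        )
        segments = segment_trials(res.timelines)
        fit = fit_controller(res.recording, segments, constraint_product=CONSTRAINT, seed=seed)
        z1.append(fit.zeta1)
        z2.append(fit.zeta2)
        true_xp = {"pre_hc": res.tasks[0].x_p, "post_hc": res.tasks[0].x_sd}
        for seg_xp, seg in zip(fit.x_p, segments):
            xp_err.append(abs(seg_xp - true_xp[seg.context]))
    return {
        "zeta1": np.array(z1),
        "zeta2": np.array(z2),
        "xp_err": np.array(xp_err),
    }
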