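import numpy as np
import pytest

from tugkit.pipeline import analyze_trajectory
from tugkit.synth import TUGScenario, generate_trajectory, random_scenario


@pytest.fixture(scope="session")
def default_trial():
    """Default scenario trajectory, ground truth and analysis result."""
    scn = TUGScenario(seed=1)
    traj, truth = generate_trajectory(scn)
    return scn, traj, truth, analyze_trajectory(traj)


@pytest.fixture(scope="session")
def clean_trial():
    """Noise-free default trajectory with ground truth."""
    scn = TUGScenario(seed=2, noise_sd=0.0)
    traj, truth = generate_trajectory(scn)
    return scn, traj, truth


@pytest.fixture(scope="session")
def segmentation_suite():
    """Analyses of the 100-seed randomized scenario suite (shared by the
    event-recovery and parameter-recovery acceptance checks)."""
    out = []
    for seed in range(100):
        scn = random_scenario(seed)
        traj, truth = generate_trajectory(scn)
        out.append((scn, truth, analyze_trajectory(traj)))
    return out


def rng(seed=0):
    return np.random.default_rng(seed)
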